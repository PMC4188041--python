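"""Sequence-only triage of mutations without informative energy predictions.

Two classifiers are combined for mutations that either lack structural
coverage or have sub-threshold ΔΔG values:

1. *Sequence conservation* — the Shannon entropy (bits) of the mutated
   alignment column in an ortholog MSA; low entropy = high conservation,
   expected for disease positions.
2. *Substitution diverseness* — the BLOSUM log-odds score of the
   wild-type → mutant exchange; low (negative) scores mark chemically
   drastic substitutions.

Both classifiers are thresholded at the mean of the disease-mutation
cohort, and the two binary calls combine to a verdict: both criteria met
→ *likely* disease-causing, one → *maybe*, neither → *unlikely*.  Buried
positions with sub-threshold energies are kept apart as
``core_subthreshold``.

The threshold-then-predict step is also exposed as a scikit-learn
estimator (:class:`SequenceTriage`): ``fit`` learns the two cohort means,
``predict`` emits verdicts.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from sklearn.base import BaseEstimator

from .catalog import AA_ALPHABET, ValidationError
from .energetics import Location, MutClass, Tier

__all__ = [
    "GAP",
    "Verdict",
    "Thresholds",
    "shannon_entropy",
    "blosum_score",
    "load_matrix",
    "default_matrix",
    "thresholds",
    "combined_verdict",
    "read_alignment",
    "column_for_position",
    "SequenceTriage",
]

GAP = "-"


class Verdict(str, enum.Enum):
    LIKELY = "likely"
    MAYBE = "maybe"
    UNLIKELY = "unlikely"
    CORE_SUBTHRESHOLD = "core_subthreshold"


@dataclass(frozen=True)
class Thresholds:
    """Disease-cohort means used as decision thresholds (strict <)."""

    entropy_mean: float
    blosum_mean: float


def shannon_entropy(column: Iterable[str]) -> float:
    """Shannon entropy (bits) of one alignment column.

    Frequencies are computed over non-gap residues only; gaps are excluded
    rather than treated as a 21st symbol, since the classifier measures
    conservation of the residue alphabet.  Bounded by [0, log2 20].
    """
    residues = [c.upper() for c in column]
    if not residues:
        raise ValidationError("empty alignment column")
    bad = sorted({c for c in residues if c != GAP and c not in AA_ALPHABET})
    if bad:
        raise ValidationError(f"invalid symbols in alignment column: {bad}")
    residues = [c for c in residues if c != GAP]
    if not residues:
        raise ValidationError("all-gap alignment column has no defined entropy")
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def default_matrix():
    """The BLOSUM62 substitution matrix (package default)."""
    return substitution_matrices.load("BLOSUM62")


def load_matrix(path: str | Path):
    """Read a substitution matrix in NCBI text format (# comments, letter header)."""
    return substitution_matrices.read(str(path))


def blosum_score(wt: str, mut: str, matrix=None) -> int:
    """Symmetric substitution-matrix lookup for a wt → mut exchange."""
    if matrix is None:
        matrix = default_matrix()
    wt, mut = wt.upper(), mut.upper()
    for letter in (wt, mut):
        if letter not in matrix.alphabet:
            raise ValidationError(f"letter {letter!r} not present in the matrix alphabet")
    return int(matrix[wt, mut])


def thresholds(entropies: Sequence[float], blosums: Sequence[float]) -> Thresholds:
    """Arithmetic means of the disease cohort's entropy and BLOSUM scores."""
    if len(entropies) == 0 or len(blosums) == 0:
        raise ValidationError("cannot compute thresholds from an empty disease set")
    return Thresholds(float(np.mean(entropies)), float(np.mean(blosums)))


def combined_verdict(
    entropy: float,
    blosum: float,
    thr: Thresholds,
    location: Location = Location.UNKNOWN,
    tier: Tier = Tier.NA,
) -> Verdict:
    """Combine the two sequence classifiers into one verdict.

    Intended for mutations with ``tier=ns`` (sub-threshold energies) or no
    structural model.  Buried sub-threshold mutations are set aside as
    ``core_subthreshold``; otherwise each criterion is met when the score
    is strictly below its disease-cohort mean, and the number of criteria
    met (2/1/0) maps to likely/maybe/unlikely.
    """
    if location is Location.CORE and tier is Tier.NS:
        return Verdict.CORE_SUBTHRESHOLD
    met = int(entropy < thr.entropy_mean) + int(blosum < thr.blosum_mean)
    return (Verdict.UNLIKELY, Verdict.MAYBE, Verdict.LIKELY)[met]


# ---------------------------------------------------------------------------
# Alignment handling


def read_alignment(path: str | Path, fmt: Optional[str] = None) -> MultipleSeqAlignment:
    """Read an MSA from FASTA or Clustal; format inferred from the suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    alignment = AlignIO.read(str(path), fmt)
    lengths = {len(rec.seq) for rec in alignment}
    if len(lengths) > 1:
        raise ValidationError(f"{path.name}: unequal sequence lengths {sorted(lengths)}")
    return alignment


def column_for_position(
    alignment: MultipleSeqAlignment, target_id: str, position: int
) -> int:
    """Map a 1-based ungapped residue position of the target sequence to a
    0-based alignment column index."""
    if position < 1:
        raise ValidationError(f"position must be >= 1, got {position}")
    for rec in alignment:
        if rec.id == target_id:
            seen = 0
            for col, symbol in enumerate(str(rec.seq)):
                if symbol != GAP:
                    seen += 1
                    if seen == position:
                        return col
            raise ValidationError(
                f"position {position} beyond the {seen}-residue target {target_id!r}"
            )
    raise ValidationError(f"target sequence {target_id!r} not in alignment")


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


class SequenceTriage(BaseEstimator):
    """Mean-threshold sequence triage as a scikit-learn style estimator.

    ``fit`` takes the *disease reference cohort* as an ``(n, 2)`` array of
    ``[entropy_bits, blosum_score]`` rows and learns the two decision
    thresholds (cohort means).  ``predict`` maps new ``(n, 2)`` rows to
    verdict strings ``"likely" / "maybe" / "unlikely"``.

    The ``core_subthreshold`` escape hatch needs structural context
    (location, tier) that is not part of the two-column feature matrix;
    use :func:`combined_verdict` when that context is available.

    Attributes
    ----------
    entropy_mean_ : float
        Mean Shannon entropy of the fitted disease cohort (bits).
    blosum_mean_ : float
        Mean substitution score of the fitted disease cohort.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] == 0:
            raise ValidationError(
                f"expected a non-empty (n, 2) [entropy, blosum] matrix, got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite scores in the disease cohort")
        self.entropy_mean_ = float(X[:, 0].mean())
        self.blosum_mean_ = float(X[:, 1].mean())
        self.n_features_in_ = 2
        return self

    @property
    def thresholds_(self) -> Thresholds:
        self._check_fitted()
        return Thresholds(self.entropy_mean_, self.blosum_mean_)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError(f"expected an (n, 2) [entropy, blosum] matrix, got {X.shape}")
        met = (X[:, 0] < self.entropy_mean_).astype(int) + (
            X[:, 1] < self.blosum_mean_
        ).astype(int)
        labels = np.array(
            [Verdict.UNLIKELY.value, Verdict.MAYBE.value, Verdict.LIKELY.value]
        )
        return labels[met]

    def _check_fitted(self) -> None:
        if not hasattr(self, "entropy_mean_"):
            raise ValidationError("SequenceTriage is not fitted; call fit() first")
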