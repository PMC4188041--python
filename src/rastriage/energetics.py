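"""ΔΔG triage of missense mutations into significance tiers and mechanistic classes.

Consumes per-mutation free-energy changes (kcal/mol) precomputed by a
structure-based force field (folding ΔΔG plus any number of interface
terms), and applies the two-threshold significance scheme:

* |ΔΔG| > 1.6 kcal/mol — highly significant (twice the force-field error SD),
* |ΔΔG| > 0.8 kcal/mol — significant (one SD),
* otherwise not significant.

Significant mutations are then assigned a mechanistic class by the nature
of the dominant (largest-|ΔΔG|) energy term:

==============  =====================================================
class           mechanism
==============  =====================================================
1a              impairs a domain-domain autoinhibitory interaction
1b              releases an inhibitory protein segment
2               perturbs a protein-protein interaction
3               destabilises a globular domain (folding)
4               alters localisation and/or half-life (literature flag)
5               neutral (no term above threshold, surface position)
core_subthresh  buried, but below the energy threshold
not_modelled    no structural coverage
==============  =====================================================

Literature knowledge overrides energies: a mutation experimentally shown
to change membrane targeting is class 4 regardless of its ΔΔG terms, and
catalytic-site mutations are recorded as activity-changing (class 1a
bucket) with ``driving_term="catalysis"``.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalog import ValidationError

__all__ = [
    "HIGH_CUTOFF",
    "SIGNIFICANT_CUTOFF",
    "Tier",
    "MutClass",
    "TermKind",
    "Location",
    "LiteratureFlag",
    "InterfaceTerm",
    "EnergyRecord",
    "ClassAssignment",
    "significance_tier",
    "classify",
    "partition_summary",
    "parse_energy_table",
    "write_energy_table",
]

#: kcal/mol, one and two standard deviations of the force-field error.
SIGNIFICANT_CUTOFF = 0.8
HIGH_CUTOFF = 1.6


class Tier(str, enum.Enum):
    HIGH = "high"
    SIGNIFICANT = "significant"
    NS = "ns"
    NA = "na"


class MutClass(str, enum.Enum):
    C1A = "1a"
    C1B = "1b"
    C2 = "2"
    C3 = "3"
    C4 = "4"
    C5 = "5"
    CORE_SUBTHRESHOLD = "core_subthreshold"
    NOT_MODELLED = "not_modelled"


class TermKind(str, enum.Enum):
    INTRA_DOMAIN = "intra_domain"
    INHIBITORY_SEGMENT = "inhibitory_segment"
    INTER_PROTEIN = "inter_protein"


class Location(str, enum.Enum):
    SURFACE = "surface"
    CORE = "core"
    UNKNOWN = "unknown"


class LiteratureFlag(str, enum.Enum):
    NONE = "none"
    CATALYSIS = "catalysis"
    MEMBRANE_LOCALISATION = "membrane_localisation"
    OTHER_LOCALISATION = "other_localisation"


#: Interface-term kind -> mechanistic class of the dominant term.
_KIND_TO_CLASS = {
    TermKind.INTRA_DOMAIN: MutClass.C1A,
    TermKind.INHIBITORY_SEGMENT: MutClass.C1B,
    TermKind.INTER_PROTEIN: MutClass.C2,
}

#: Exact-tie precedence: folding before the interface kinds.
_TIE_ORDER = {
    "fold": 0,
    TermKind.INTRA_DOMAIN.value: 1,
    TermKind.INHIBITORY_SEGMENT.value: 2,
    TermKind.INTER_PROTEIN.value: 3,
}


@dataclass(frozen=True)
class InterfaceTerm:
    partner: str
    kind: TermKind
    ddg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValidationError(f"non-finite interface ΔΔG for partner {self.partner!r}")


@dataclass(frozen=True)
class EnergyRecord:
    """Per-mutation energy record as produced by an external force field.

    ``ddg_fold`` is the folding free-energy change (positive =
    destabilising); ``interface_terms`` carries one signed ΔΔG per
    modelled interface.  ``has_structure=False`` means the mutation lacks
    3D coverage, in which case no energies may be present.
    """

    gene: str
    position: int
    wt_aa: str
    mut_aa: str
    has_structure: bool
    ddg_fold: Optional[float] = None
    interface_terms: tuple[InterfaceTerm, ...] = ()
    location: Location = Location.UNKNOWN
    literature_flag: LiteratureFlag = LiteratureFlag.NONE

    def __post_init__(self) -> None:
        if not self.has_structure and (self.ddg_fold is not None or self.interface_terms):
            raise ValidationError(
                f"{self.gene} {self.wt_aa}{self.position}{self.mut_aa}: energies "
                "present but has_structure is false"
            )
        if self.ddg_fold is not None and not math.isfinite(self.ddg_fold):
            raise ValidationError("non-finite folding ΔΔG")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene, self.position, self.wt_aa, self.mut_aa)

    def terms(self) -> list[tuple[str, Optional[str], float]]:
        """All energy terms as (kind, partner, ddg); folding kind is ``"fold"``."""
        out: list[tuple[str, Optional[str], float]] = []
        if self.ddg_fold is not None:
            out.append(("fold", None, self.ddg_fold))
        out.extend((t.kind.value, t.partner, t.ddg) for t in self.interface_terms)
        return out

    def max_abs_ddg(self) -> Optional[float]:
        """Signed value of the largest-|ΔΔG| term, or None if unmodelled."""
        terms = self.terms()
        if not terms:
            return None
        return max(terms, key=lambda t: abs(t[2]))[2]


@dataclass(frozen=True)
class ClassAssignment:
    klass: MutClass
    tier: Tier
    #: (kind, partner, ddg) of the term that decided the class; the string
    #: "catalysis" for literature catalytic-site mutations; None otherwise.
    driving_term: Optional[tuple[str, Optional[str], float] | str] = None


def significance_tier(ddg: float) -> Tier:
    """Map one |ΔΔG| onto the three-tier significance scheme (strict >)."""
    if not math.isfinite(ddg):
        raise ValidationError(f"non-finite ΔΔG: {ddg!r}")
    mag = abs(ddg)
    if mag > HIGH_CUTOFF:
        return Tier.HIGH
    if mag > SIGNIFICANT_CUTOFF:
        return Tier.SIGNIFICANT
    return Tier.NS


def _dominant_term(record: EnergyRecord) -> Optional[tuple[str, Optional[str], float]]:
    terms = record.terms()
    if not terms:
        return None
    # Largest |ΔΔG| wins; exact ties by fixed precedence fold > intra_domain
    # > inhibitory_segment > inter_protein.
    return min(terms, key=lambda t: (-abs(t[2]), _TIE_ORDER[t[0]]))


def classify(record: EnergyRecord) -> ClassAssignment:
    """Assign one mutation to its mechanistic class and significance tier.

    Literature flags take precedence over energies; otherwise the dominant
    energy term above the 0.8 kcal/mol cut-off decides the class, falling
    back to ``core_subthreshold`` / ``5`` (neutral) below threshold and
    ``not_modelled`` without structural coverage.  Deterministic and total
    on valid records.
    """
    flag = record.literature_flag
    if flag in (LiteratureFlag.MEMBRANE_LOCALISATION, LiteratureFlag.OTHER_LOCALISATION):
        return ClassAssignment(MutClass.C4, Tier.NA, None)
    if flag is LiteratureFlag.CATALYSIS:
        return ClassAssignment(MutClass.C1A, Tier.NA, "catalysis")
    if not record.has_structure:
        return ClassAssignment(MutClass.NOT_MODELLED, Tier.NA, None)
    dom = _dominant_term(record)
    if dom is not None and abs(dom[2]) > SIGNIFICANT_CUTOFF:
        kind = dom[0]
        klass = MutClass.C3 if kind == "fold" else _KIND_TO_CLASS[TermKind(kind)]
        return ClassAssignment(klass, significance_tier(dom[2]), dom)
    if record.location is Location.CORE:
        return ClassAssignment(MutClass.CORE_SUBTHRESHOLD, Tier.NS, dom)
    return ClassAssignment(MutClass.C5, Tier.NS, dom)


_INTERACTION_CLASSES = {MutClass.C1A, MutClass.C1B, MutClass.C2}


def _energy_fractions(pairs, tiers: set[Tier]) -> tuple[Optional[float], Optional[float], int]:
    interaction = folding = 0
    for _rec, asg in pairs:
        if asg.tier in tiers and isinstance(asg.driving_term, tuple):
            if asg.klass in _INTERACTION_CLASSES:
                interaction += 1
            elif asg.klass is MutClass.C3:
                folding += 1
    denom = interaction + folding
    if denom == 0:
        return None, None, 0
    return interaction / denom, folding / denom, denom


def partition_summary(records: Sequence[EnergyRecord]) -> dict:
    """Partition a classified cohort into the headline summary counts.

    Returns a dict with the structural-coverage split, the
    significant-or-literature-flagged count among modelled mutations, the
    highly significant count, and the interaction-vs-folding fractions of
    the energy-driven classes.  Fractions are reported over two
    denominators — the highly significant set and the full significant set
    — because published summaries differ on which is meant.
    """
    pairs = [(rec, classify(rec)) for rec in records]
    modelled = [(r, a) for r, a in pairs if r.has_structure]
    not_modelled = len(pairs) - len(modelled)
    sig_or_flagged = sum(
        1
        for r, a in modelled
        if a.tier in (Tier.HIGH, Tier.SIGNIFICANT) or r.literature_flag is not LiteratureFlag.NONE
    )
    highly = sum(1 for _r, a in modelled if a.tier is Tier.HIGH)
    inter_hi, fold_hi, n_hi = _energy_fractions(modelled, {Tier.HIGH})
    inter_sig, fold_sig, n_sig = _energy_fractions(modelled, {Tier.HIGH, Tier.SIGNIFICANT})
    return {
        "n_input": len(pairs),
        "modelled": len(modelled),
        "not_modelled": not_modelled,
        "significant_or_flagged": sig_or_flagged,
        "highly_significant": highly,
        "ns": len(modelled) - sig_or_flagged,
        "interaction_fraction": inter_hi,
        "folding_fraction": fold_hi,
        "interaction_fraction_significant": inter_sig,
        "folding_fraction_significant": fold_sig,
        "n_energy_driven_high": n_hi,
        "n_energy_driven_significant": n_sig,
    }


# ---------------------------------------------------------------------------
# Table I/O: tab-separated with repeating (kind, partner, ddg) term triplets.

_FIXED_LEAD = ["gene", "position", "wt_aa", "mut_aa", "has_structure", "ddg_fold"]
_FIXED_TAIL = ["location", "literature_flag"]


def write_energy_table(records: Iterable[EnergyRecord], path: str | Path) -> None:
    """Write records as a TSV with repeating term triplet columns."""
    records = list(records)
    n_terms = max((len(r.interface_terms) for r in records), default=0)
    term_cols = [
        f"term_{part}_{i + 1}" for i in range(n_terms) for part in ("kind", "partner", "ddg")
    ]
    rows = []
    for r in records:
        row = {
            "gene": r.gene,
            "position": r.position,
            "wt_aa": r.wt_aa,
            "mut_aa": r.mut_aa,
            "has_structure": int(r.has_structure),
            "ddg_fold": "" if r.ddg_fold is None else format(r.ddg_fold, ".17g"),
            "location": r.location.value,
            "literature_flag": r.literature_flag.value,
        }
        for i, t in enumerate(r.interface_terms):
            row[f"term_kind_{i + 1}"] = t.kind.value
            row[f"term_partner_{i + 1}"] = t.partner
            row[f"term_ddg_{i + 1}"] = format(t.ddg, ".17g")
        rows.append(row)
    df = pd.DataFrame(rows, columns=_FIXED_LEAD + term_cols + _FIXED_TAIL)
    df.to_csv(path, sep="\t", index=False)


def parse_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read an energy table written by :func:`write_energy_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_LEAD + _FIXED_TAIL if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    n_terms = sum(1 for c in df.columns if c.startswith("term_kind_"))
    records: list[EnergyRecord] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            terms = []
            for i in range(1, n_terms + 1):
                kind = d.get(f"term_kind_{i}", "").strip()
                ddg = d.get(f"term_ddg_{i}", "").strip()
                if not kind and not ddg:
                    continue
                if not kind:
                    raise ValidationError(
                        f"term {i}: energy {ddg!r} present without a term kind"
                    )
                terms.append(
                    InterfaceTerm(
                        partner=d.get(f"term_partner_{i}", "").strip(),
                        kind=TermKind(kind),
                        ddg=float(ddg),
                    )
                )
            ddg_fold = d["ddg_fold"].strip()
            records.append(
                EnergyRecord(
                    gene=d["gene"].strip(),
                    position=int(d["position"]),
                    wt_aa=d["wt_aa"].strip(),
                    mut_aa=d["mut_aa"].strip(),
                    has_structure=bool(int(d["has_structure"])),
                    ddg_fold=float(ddg_fold) if ddg_fold else None,
                    interface_terms=tuple(terms),
                    location=Location(d["location"].strip()),
                    literature_flag=LiteratureFlag(d["literature_flag"].strip()),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError(
            f"{path.name}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records
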