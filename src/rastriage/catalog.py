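"""Missense-mutation catalogue handling.

Reads, validates, de-duplicates and summarises catalogues of disease
missense mutations (RASopathy germline and cancer somatic), and maps each
mutation onto a gene's structural regions — Pfam-style domains, the
inter-domain regions between them ("I1" … "Ix"), and the terminal tails
("N", "C").

The catalogue file is a tab- or comma-separated table with header columns
``gene, position, wt_aa, mut_aa, origin, disease, gold_set``.  Residue
numbering is 1-based and region intervals are closed, matching standard
protein-mutation nomenclature.
"""
from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "Origin",
    "MutationRecord",
    "Region",
    "RegionKind",
    "RegionMap",
    "OriginSummary",
    "ValidationError",
    "parse_mutations",
    "parse_regions",
    "origin_summary",
    "assign_region",
    "region_counts",
]

#: The 20 standard one-letter amino-acid codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

CATALOG_COLUMNS = ("gene", "position", "wt_aa", "mut_aa", "origin", "disease", "gold_set")

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


class ValidationError(ValueError):
    """Raised when an input table or record violates the format contract."""


class Origin(str, enum.Enum):
    """Mutation origin: Mendelian germline, somatic (cancer), or both."""

    GERMLINE = "germline"
    SOMATIC = "somatic"
    BOTH = "both"


@dataclass(frozen=True)
class MutationRecord:
    """One curated missense mutation.

    Parameters
    ----------
    gene : str
        Gene symbol (e.g. ``KRAS``).
    position : int
        1-based residue index of the substitution.
    wt_aa, mut_aa : str
        Wild-type and mutant one-letter amino acids; must differ and both
        be members of the 20-letter alphabet.
    origin : Origin
        Whether the mutation is germline, somatic, or reported as both.
    disease_labels : tuple of str
        Free-text disease annotations (syndrome or tumour type names).
    gold_set : bool
        Member of the experimentally validated "gold set" used for the
        germline-vs-cancer energy comparison.
    """

    gene: str
    position: int
    wt_aa: str
    mut_aa: str
    origin: Origin
    disease_labels: tuple[str, ...] = ()
    gold_set: bool = False

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET:
            raise ValidationError(f"invalid wild-type amino acid {self.wt_aa!r}")
        if self.mut_aa not in AA_ALPHABET:
            raise ValidationError(f"invalid mutant amino acid {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"{self.gene} position {self.position}: wt and mutant amino acid "
                f"are both {self.wt_aa!r} (synonymous rows are not missense mutations)"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """De-duplication key: (gene, position, wt_aa, mut_aa)."""
        return (self.gene, self.position, self.wt_aa, self.mut_aa)

    def __str__(self) -> str:  # e.g. "KRAS G12V"
        return f"{self.gene} {self.wt_aa}{self.position}{self.mut_aa}"


class RegionKind(str, enum.Enum):
    DOMAIN = "domain"
    INTER_DOMAIN = "inter_domain"
    N_TERM = "n_term"
    C_TERM = "c_term"


@dataclass(frozen=True)
class Region:
    label: str
    start: int
    end: int
    kind: RegionKind

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"region {self.label!r}: invalid interval [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class RegionMap:
    """Ordered, non-overlapping structural regions of one gene product."""

    gene: str
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{self.gene}: duplicate region labels")
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.gene}: regions {a.label!r} and {b.label!r} overlap "
                    f"or are out of order"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)


@dataclass(frozen=True)
class OriginSummary:
    """Disjoint origin counts plus the inclusive counting conventions.

    ``n_germline``/``n_somatic`` count records whose origin is exclusively
    germline or somatic; ``n_both`` counts records reported in both
    settings.  Published summaries are sometimes ambiguous about whether
    dual mutations are counted inside the per-origin totals, so
    :meth:`conventions` reports all three readings.
    """

    n_germline: int
    n_somatic: int
    n_both: int

    def conventions(self) -> dict[str, tuple[int, int, int]]:
        g, s, b = self.n_germline, self.n_somatic, self.n_both
        return {
            "exclusive": (g, s, b),
            "inclusive_germline": (g + b, s, b),
            "inclusive_somatic": (g, s + b, b),
            "inclusive_both": (g + b, s + b, b),
        }

    def __iter__(self):
        return iter((self.n_germline, self.n_somatic, self.n_both))


def _parse_bool(value: object) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text == "nan":
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean gold_set flag")


def _merge_origin(a: Origin, b: Origin) -> Origin:
    if a == b:
        return a
    return Origin.BOTH


def parse_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a mutation catalogue table into validated, de-duplicated records.

    Duplicates are keyed by (gene, position, wt_aa, mut_aa); a substitution
    appearing with both germline and somatic origin collapses to
    ``origin=both``.  De-duplication ignores ``disease_labels`` (labels are
    unioned) and ORs the ``gold_set`` flag.

    Raises
    ------
    ValidationError
        If a mandatory column is missing (file-level), or if any row has a
        malformed amino acid / position (record-level; the message lists
        the offending row numbers).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing mandatory column(s) {missing}")

    merged: dict[tuple, MutationRecord] = {}
    row_errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            origin = Origin(str(row.origin).strip().lower())
            labels = tuple(
                sorted({s.strip() for s in str(row.disease).split(";") if s.strip()})
            )
            rec = MutationRecord(
                gene=str(row.gene).strip(),
                position=int(row.position),
                wt_aa=str(row.wt_aa).strip().upper(),
                mut_aa=str(row.mut_aa).strip().upper(),
                origin=origin,
                disease_labels=labels,
                gold_set=_parse_bool(row.gold_set),
            )
        except (ValidationError, ValueError) as exc:
            row_errors.append(f"row {idx}: {exc}")
            continue
        prev = merged.get(rec.key)
        if prev is None:
            merged[rec.key] = rec
        else:
            merged[rec.key] = replace(
                prev,
                origin=_merge_origin(prev.origin, rec.origin),
                disease_labels=tuple(sorted(set(prev.disease_labels) | set(rec.disease_labels))),
                gold_set=prev.gold_set or rec.gold_set,
            )
    if row_errors:
        raise ValidationError(
            f"{path.name}: {len(row_errors)} invalid row(s):\n" + "\n".join(row_errors)
        )
    return list(merged.values())


def parse_regions(path: str | Path) -> dict[str, RegionMap]:
    """Read a tab-separated region map (``gene, label, start, end, kind``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "label", "start", "end", "kind") if c not in df.columns]
    if missing:
        raise ValidationError(f"{Path(path).name}: missing column(s) {missing}")
    maps: dict[str, RegionMap] = {}
    for gene, sub in df.groupby("gene", sort=False):
        regions = tuple(
            Region(
                label=str(r.label),
                start=int(r.start),
                end=int(r.end),
                kind=RegionKind(str(r.kind)),
            )
            for r in sub.itertuples(index=False)
        )
        regions = tuple(sorted(regions, key=lambda r: r.start))
        maps[str(gene)] = RegionMap(gene=str(gene), regions=regions)
    return maps


def origin_summary(records: Iterable[MutationRecord]) -> OriginSummary:
    """Count records by origin into three disjoint buckets."""
    g = s = b = 0
    for rec in records:
        if rec.origin is Origin.GERMLINE:
            g += 1
        elif rec.origin is Origin.SOMATIC:
            s += 1
        else:
            b += 1
    return OriginSummary(g, s, b)


def assign_region(record: MutationRecord, region_map: RegionMap) -> str:
    """Assign a mutation to exactly one structural-region label.

    Positions before the first declared region map to ``"N"``, positions
    after the last to ``"C"``.  Positions inside a gap between two declared
    regions are absorbed into the preceding region, so the assignment is
    total: inter-domain regions tile the space between domains.
    """
    regions = region_map.regions
    if not regions:
        raise ValidationError(f"{region_map.gene}: empty region map")
    pos = record.position
    if pos < regions[0].start:
        return "N"
    if pos > regions[-1].end:
        return "C"
    i = bisect_right([r.start for r in regions], pos) - 1
    return regions[i].label


def region_counts(
    records: Sequence[MutationRecord],
    region_maps: Mapping[str, RegionMap],
) -> pd.DataFrame:
    """Per-(gene, region, origin) mutation counts.

    Returns a DataFrame indexed by ``(gene, region)`` with integer columns
    ``germline``, ``somatic`` and ``both``.  Every declared region of every
    gene in ``region_maps`` is retained (zero-filled), plus the "N" and
    "C" tails, so the table layout is independent of which regions happen
    to carry mutations.  Counts sum to ``len(records)`` provided every
    record's gene has a region map.
    """
    index = pd.MultiIndex.from_tuples(
        [
            (gene, label)
            for gene, rmap in region_maps.items()
            for label in ("N", *rmap.labels, "C")
        ],
        names=["gene", "region"],
    )
    table = pd.DataFrame(0, index=index, columns=[o.value for o in Origin], dtype=int)
    for rec in records:
        try:
            rmap = region_maps[rec.gene]
        except KeyError:
            raise ValidationError(f"no region map for gene {rec.gene!r}") from None
        label = assign_region(rec, rmap)
        table.loc[(rec.gene, label), rec.origin.value] += 1
    return table
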