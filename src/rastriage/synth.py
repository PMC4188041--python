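"""Synthetic-data generator for every input the triage pipeline consumes.

Generates mutation catalogues, energy tables, ortholog alignments, region
maps and mutant fold-change sets with the statistical structure the
analysis assumes, so the whole pipeline is testable offline:

* catalogue origin counts are configurable (defaults: 295 germline-only,
  603 somatic-only, 58 dual — the disjoint convention, which also fixes
  the 956 total);
* the somatic ΔΔG distribution sits above the germline one (normal
  distributions with configurable means and a common SD);
* mechanistic class structure is injected through the kind of the
  dominant energy term, per a configurable class mix;
* alignment columns hit prescribed target entropies via a
  point-mass/uniform mixture over the 20 amino acids;
* fold-change sets include a GAP-insensitive oncogenic-like variant and
  partly compensatory variants (GEF and GAP losses combined).

All generators are pure functions of (seed, config): the same seed gives
byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .catalog import AA_ALPHABET, Origin, Region, RegionKind, RegionMap, ValidationError
from .energetics import (
    EnergyRecord,
    InterfaceTerm,
    LiteratureFlag,
    Location,
    MutClass,
    TermKind,
    write_energy_table,
)
from .rascycle import FoldChangeSet

__all__ = [
    "STUDY_GENES",
    "SynthConfig",
    "gen_catalog",
    "gen_energy_table",
    "gen_msa",
    "gen_fold_changes",
    "gen_region_maps",
    "gen_grouped_ddg",
    "gen_random_energy_records",
    "gen_random_model_params",
    "write_dataset",
    "target_entropy_distribution",
]

#: The 15 genes of the Ras/MAPK disease network.
STUDY_GENES = (
    "PTPN11", "SOS1", "RASA1", "NF1", "KRAS", "HRAS", "NRAS", "BRAF",
    "RAF1", "MAP2K1", "MAP2K2", "SPRED1", "RIT1", "SHOC2", "CBL",
)

_AAS = np.array(sorted(AA_ALPHABET))
_LOG2_20 = math.log2(20)

_GERMLINE_LABELS = ("Noonan syndrome", "CFC syndrome", "Costello syndrome", "LEOPARD syndrome")
_SOMATIC_LABELS = ("colorectal cancer", "melanoma", "lung adenocarcinoma", "JMML")

_CLASS_TO_KIND = {
    MutClass.C1A: TermKind.INTRA_DOMAIN,
    MutClass.C1B: TermKind.INHIBITORY_SEGMENT,
    MutClass.C2: TermKind.INTER_PROTEIN,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 295/603/58 origin counts, 65%
    structural coverage, 82% surface positions, overlapping per-origin
    ΔΔG distributions with the somatic mean above the germline one, and a
    class mix whose interaction:folding split among significant classes
    is ≈65:35.
    """

    seed: int = 0
    n_germline: int = 295
    n_somatic: int = 603
    n_both: int = 58
    germline_ddg_mean: float = 1.0   # kcal/mol
    somatic_ddg_mean: float = 2.0    # kcal/mol
    ddg_sd: float = 1.5              # kcal/mol, common to both origins
    fraction_structured: float = 0.65
    fraction_surface: float = 0.82
    flag_fraction: float = 0.03      # literature-flagged share of structured records
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"1a": 0.20, "1b": 0.09, "2": 0.20, "3": 0.26, "5": 0.25}
    )
    n_gold_per_origin: int = 20
    msa_depth: int = 200
    conservation_profile: tuple[float, ...] = (
        0.0, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0,
        0.1, 0.8, 1.2, 2.2, 3.2, 0.4, 1.8, 2.8, 3.8, _LOG2_20,
    )
    variant_fold_changes: tuple[FoldChangeSet, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_germline", "n_somatic", "n_both", "msa_depth"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("fraction_structured", "fraction_surface", "flag_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if not math.isclose(sum(self.class_mix.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("class_mix proportions must sum to 1")
        if set(self.class_mix) - {"1a", "1b", "2", "3", "5"}:
            raise ValidationError(f"unknown class_mix keys: {set(self.class_mix) - {'1a','1b','2','3','5'}}")
        if self.somatic_ddg_mean < self.germline_ddg_mean:
            raise ValidationError(
                "somatic_ddg_mean must be >= germline_ddg_mean (the emulated effect direction)"
            )
        if self.ddg_sd <= 0:
            raise ValidationError("ddg_sd must be > 0")
        for h in self.conservation_profile:
            if not 0.0 <= h <= _LOG2_20 + 1e-12:
                raise ValidationError(f"target entropy {h} outside [0, log2 20]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if "conservation_profile" in cfg:
            cfg["conservation_profile"] = tuple(float(h) for h in cfg["conservation_profile"])
        if "variant_fold_changes" in cfg:
            cfg["variant_fold_changes"] = tuple(
                FoldChangeSet(name=name, **{k: float(v) for k, v in spec.items()})
                for name, spec in cfg["variant_fold_changes"].items()
            )
        return cls(**cfg)


def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


def _draw_substitution(rng: np.random.Generator) -> tuple[str, str]:
    wt = _AAS[rng.integers(len(_AAS))]
    mut = wt
    while mut == wt:
        mut = _AAS[rng.integers(len(_AAS))]
    return str(wt), str(mut)


def gen_catalog(config: SynthConfig, path: str | Path) -> Path:
    """Write a synthetic mutation catalogue with the configured origin counts.

    Mutation keys (gene, position, wt, mut) are unique by construction, so
    the catalogue round-trips through the parser to exactly the requested
    counts.  Deterministic given the seed.
    """
    rng = _rng(config, 1)
    counts = (
        (Origin.GERMLINE, config.n_germline),
        (Origin.SOMATIC, config.n_somatic),
        (Origin.BOTH, config.n_both),
    )
    used: set[tuple] = set()
    rows: list[dict] = []
    for origin, n in counts:
        made = 0
        while made < n:
            gene = str(STUDY_GENES[rng.integers(len(STUDY_GENES))])
            position = int(rng.integers(1, 601))
            wt, mut = _draw_substitution(rng)
            key = (gene, position, wt, mut)
            if key in used:
                continue
            used.add(key)
            if origin is Origin.GERMLINE:
                disease = _GERMLINE_LABELS[rng.integers(len(_GERMLINE_LABELS))]
            elif origin is Origin.SOMATIC:
                disease = _SOMATIC_LABELS[rng.integers(len(_SOMATIC_LABELS))]
            else:
                disease = (
                    _GERMLINE_LABELS[rng.integers(len(_GERMLINE_LABELS))]
                    + ";"
                    + _SOMATIC_LABELS[rng.integers(len(_SOMATIC_LABELS))]
                )
            rows.append(
                {
                    "gene": gene,
                    "position": position,
                    "wt_aa": wt,
                    "mut_aa": mut,
                    "origin": origin.value,
                    "disease": disease,
                    "gold_set": 0,
                }
            )
            made += 1
    # Gold set: experimentally validated members from each origin.
    for origin in (Origin.GERMLINE, Origin.SOMATIC):
        candidates = [r for r in rows if r["origin"] == origin.value]
        chosen = rng.choice(len(candidates), size=min(config.n_gold_per_origin, len(candidates)), replace=False)
        for i in chosen:
            candidates[i]["gold_set"] = 1
    path = Path(path)
    lines = ["\t".join(("gene", "position", "wt_aa", "mut_aa", "origin", "disease", "gold_set"))]
    for r in rows:
        lines.append(
            "\t".join(
                str(r[c]) for c in ("gene", "position", "wt_aa", "mut_aa", "origin", "disease", "gold_set")
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def gen_grouped_ddg(
    config: SynthConfig,
    n_germline: int,
    n_somatic: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw germline and somatic ΔΔG samples from the configured
    per-origin normal distributions (the energy table uses the same law)."""
    if rng is None:
        rng = _rng(config, 5)
    g = rng.normal(config.germline_ddg_mean, config.ddg_sd, size=n_germline)
    s = rng.normal(config.somatic_ddg_mean, config.ddg_sd, size=n_somatic)
    return g, s


def _origin_mean(config: SynthConfig, origin: str) -> float:
    if origin == Origin.GERMLINE.value:
        return config.germline_ddg_mean
    if origin == Origin.SOMATIC.value:
        return config.somatic_ddg_mean
    return 0.5 * (config.germline_ddg_mean + config.somatic_ddg_mean)


def gen_energy_table(config: SynthConfig, catalog_records, path: str | Path) -> Path:
    """Write a synthetic energy table matched to a parsed catalogue.

    A ``fraction_structured`` share of records receives energies.  Each
    structured record draws a mechanistic class from ``class_mix`` and a
    driving ΔΔG from its origin's normal distribution; the driving value
    lands on the term kind of the drawn class (folding ΔΔG for class 3,
    an interface term otherwise), with sub-threshold noise on the other
    terms.  Class-5 records draw strictly sub-threshold values.  A small
    ``flag_fraction`` carries literature flags.
    """
    rng = _rng(config, 2)
    records: list[EnergyRecord] = []
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[k] for k in classes])
    for rec in catalog_records:
        structured = bool(rng.random() < config.fraction_structured)
        flag = LiteratureFlag.NONE
        if structured and rng.random() < config.flag_fraction:
            flag = (
                LiteratureFlag.CATALYSIS,
                LiteratureFlag.MEMBRANE_LOCALISATION,
                LiteratureFlag.OTHER_LOCALISATION,
            )[rng.choice(3, p=[0.5, 0.25, 0.25])]
        if not structured:
            records.append(
                EnergyRecord(
                    gene=rec.gene,
                    position=rec.position,
                    wt_aa=rec.wt_aa,
                    mut_aa=rec.mut_aa,
                    has_structure=False,
                    location=Location.UNKNOWN,
                    literature_flag=flag if flag in (
                        LiteratureFlag.MEMBRANE_LOCALISATION,
                        LiteratureFlag.OTHER_LOCALISATION,
                    ) else LiteratureFlag.NONE,
                )
            )
            continue
        location = Location.SURFACE if rng.random() < config.fraction_surface else Location.CORE
        klass = MutClass(classes[rng.choice(len(classes), p=probs)])
        value = float(rng.normal(_origin_mean(config, rec.origin.value), config.ddg_sd))
        ddg_fold: Optional[float] = None
        terms: list[InterfaceTerm] = []
        if klass is MutClass.C5:
            ddg_fold = float(rng.uniform(0.0, 0.75))
        elif klass is MutClass.C3:
            ddg_fold = value
        else:
            kind = _CLASS_TO_KIND[klass]
            terms.append(InterfaceTerm(partner=f"{rec.gene}_partner", kind=kind, ddg=value))
            ddg_fold = float(rng.uniform(-0.5, 0.5))  # sub-threshold background
        records.append(
            EnergyRecord(
                gene=rec.gene,
                position=rec.position,
                wt_aa=rec.wt_aa,
                mut_aa=rec.mut_aa,
                has_structure=True,
                ddg_fold=ddg_fold,
                interface_terms=tuple(terms),
                location=location,
                literature_flag=flag,
            )
        )
    path = Path(path)
    write_energy_table(records, path)
    return path


def target_entropy_distribution(target_bits: float) -> np.ndarray:
    """Amino-acid distribution over the 20 letters whose Shannon entropy
    equals ``target_bits``, from the point-mass/uniform mixture family
    p = λ·δ + (1−λ)·U(20)."""
    if not 0.0 <= target_bits <= _LOG2_20 + 1e-12:
        raise ValidationError(f"target entropy {target_bits} outside [0, log2 20]")

    def entropy_of(lam: float) -> float:
        pd = lam + (1.0 - lam) / 20.0
        po = (1.0 - lam) / 20.0
        h = -pd * math.log2(pd)
        if po > 0:
            h -= 19.0 * po * math.log2(po)
        return h

    if target_bits >= _LOG2_20:
        lam = 0.0
    elif target_bits <= 0.0:
        lam = 1.0
    else:
        lam = brentq(lambda L: entropy_of(L) - target_bits, 0.0, 1.0, xtol=1e-14)
    p = np.full(20, (1.0 - lam) / 20.0)
    p[0] += lam
    return p


def gen_msa(config: SynthConfig, gene: str, path: str | Path) -> Path:
    """Write a FASTA ortholog alignment with per-column target entropies.

    Column ``j`` draws residues i.i.d. from a distribution whose exact
    entropy is ``conservation_profile[j]``, so the empirical column
    entropy converges to the target as ``msa_depth`` grows.  The first
    sequence (``<gene>_HUMAN``) is the ungapped target: the dominant
    residue of every column.
    """
    gene_stream = int.from_bytes(gene.encode(), "big") % (2**31)
    rng = _rng(config, 3, gene_stream)
    length = len(config.conservation_profile)
    if length == 0:
        raise ValidationError("conservation_profile must be non-empty")
    columns = []
    target_residues = []
    for h in config.conservation_profile:
        p = target_entropy_distribution(h)
        order = rng.permutation(20)  # dominant residue varies per column
        p = p[np.argsort(order)]
        dominant = _AAS[order[0]]
        target_residues.append(str(dominant))
        columns.append(rng.choice(_AAS, size=config.msa_depth - 1, p=p))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{gene}_HUMAN\n{''.join(target_residues)}\n")
        for i in range(config.msa_depth - 1):
            seq = "".join(str(columns[j][i]) for j in range(length))
            fh.write(f">{gene}_ortholog_{i + 1}\n{seq}\n")
    return path


def gen_fold_changes(config: SynthConfig) -> list[FoldChangeSet]:
    """Named mutant fold-change sets for variant-comparison studies.

    Unless the config supplies its own list, returns the wild type, a
    GAP-insensitive oncogenic-like reference, pure GAP-loss variants, and
    partly compensatory variants sharing the same GAP loss plus a reduced
    GEF-catalysed activation — the ordering-test construction
    WT ≤ compensatory ≤ GAP-loss.
    """
    if config.variant_fold_changes:
        return list(config.variant_fold_changes)
    return [
        FoldChangeSet(name="WT"),
        FoldChangeSet(name="oncogenic_reference", gap=0.001, intrinsic_hydrolysis=0.2),
        FoldChangeSet(name="gap_loss", gap=0.02, intrinsic_hydrolysis=0.2),
        FoldChangeSet(name="compensatory", gef=0.4, gap=0.02, intrinsic_hydrolysis=0.2),
        FoldChangeSet(name="gap_loss_mild", gap=0.05, intrinsic_hydrolysis=0.5),
        FoldChangeSet(name="compensatory_mild", gef=0.6, gap=0.05, intrinsic_hydrolysis=0.5),
    ]


def gen_random_energy_records(rng: np.random.Generator, n: int) -> list[EnergyRecord]:
    """Random rule-exercising energy records for classifier stress tests.

    Deliberately covers the awkward corners: records without structure,
    empty term lists, signed ΔΔG values concentrated around the 0.8 and
    1.6 kcal/mol cut-offs (including exact boundary values), exact-tie
    magnitudes between terms, every location and literature flag.
    """
    kinds = list(TermKind)
    locations = list(Location)
    flags = list(LiteratureFlag)
    boundary_pool = np.array([-1.6, -0.8, 0.8, 1.6, 0.0])
    records: list[EnergyRecord] = []
    for i in range(n):
        flag = flags[rng.choice(len(flags), p=[0.82, 0.06, 0.06, 0.06])]
        structured = bool(rng.random() < 0.75)
        wt, mut = _draw_substitution(rng)
        if not structured:
            records.append(
                EnergyRecord(
                    gene=str(STUDY_GENES[rng.integers(len(STUDY_GENES))]),
                    position=i + 1,
                    wt_aa=wt,
                    mut_aa=mut,
                    has_structure=False,
                    location=locations[rng.integers(3)],
                    literature_flag=flag,
                )
            )
            continue

        def draw_ddg() -> float:
            u = rng.random()
            if u < 0.15:  # exact boundary / zero values
                return float(boundary_pool[rng.integers(len(boundary_pool))])
            if u < 0.55:  # near the cut-offs
                return float(rng.uniform(-2.0, 2.0))
            return float(rng.uniform(-6.0, 6.0))

        ddg_fold = draw_ddg() if rng.random() < 0.8 else None
        n_terms = int(rng.integers(0, 4))
        terms = []
        for j in range(n_terms):
            ddg = draw_ddg()
            if terms and rng.random() < 0.2:  # exact-tie magnitudes
                ddg = math.copysign(abs(terms[-1].ddg), ddg)
            elif ddg_fold is not None and rng.random() < 0.1:
                ddg = math.copysign(abs(ddg_fold), ddg)
            terms.append(
                InterfaceTerm(
                    partner=f"P{j}", kind=kinds[rng.integers(len(kinds))], ddg=ddg
                )
            )
        records.append(
            EnergyRecord(
                gene=str(STUDY_GENES[rng.integers(len(STUDY_GENES))]),
                position=i + 1,
                wt_aa=wt,
                mut_aa=mut,
                has_structure=True,
                ddg_fold=ddg_fold,
                interface_terms=tuple(terms),
                location=locations[rng.integers(3)],
                literature_flag=flag,
            )
        )
    return records


def gen_random_model_params(
    rng: np.random.Generator, volume: float = 1e-14
) -> "RasModelParams":
    """Random but physically plausible Ras-cycle parameter sets
    (log-uniform rates and abundances) for solver robustness studies."""
    from .rascycle import RasModelParams

    def loguniform(lo: float, hi: float) -> float:
        return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))

    return RasModelParams(
        ras_total=loguniform(1e3, 1e4),
        gef_total=loguniform(3e1, 1e3),
        gap_total=loguniform(3e1, 1e3),
        eff_total=loguniform(3e2, 3e3),
        volume=volume,
        k_gef=loguniform(0.1, 100.0),
        k_gap=loguniform(0.1, 100.0),
        k_gdp_exch_intr=loguniform(1e-5, 1e-3),
        k_gtp_hydr_intr=loguniform(1e-5, 1e-3),
        kon_gef=loguniform(1e5, 1e8),
        koff_gef=loguniform(1e-2, 1e1),
        kon_gap=loguniform(1e5, 1e8),
        koff_gap=loguniform(1e-2, 1e1),
        kon_eff=loguniform(1e5, 1e8),
        koff_eff=loguniform(1e-2, 1e2),
    )


def gen_region_maps(
    genes: Sequence[str] = ("KRAS", "PTPN11"),
    seed: int = 0,
    path: Optional[str | Path] = None,
) -> dict[str, RegionMap]:
    """Deterministic synthetic region maps: alternating domains (D1…) and
    inter-domain regions (I1…) tiling part of each gene, leaving N/C tails.
    Optionally also written as the tab-separated region-map format."""
    rng = np.random.default_rng([seed % (2**31), 4])
    maps: dict[str, RegionMap] = {}
    for gene in genes:
        regions: list[Region] = []
        pos = int(rng.integers(5, 30))
        n_domains = int(rng.integers(2, 5))
        for d in range(1, n_domains + 1):
            end = pos + int(rng.integers(40, 120))
            regions.append(Region(label=f"D{d}", start=pos, end=end, kind=RegionKind.DOMAIN))
            pos = end + 1
            if d < n_domains:
                iend = pos + int(rng.integers(5, 40))
                regions.append(
                    Region(label=f"I{d}", start=pos, end=iend, kind=RegionKind.INTER_DOMAIN)
                )
                pos = iend + 1
        maps[gene] = RegionMap(gene=gene, regions=tuple(regions))
    if path is not None:
        lines = ["\t".join(("gene", "label", "start", "end", "kind"))]
        for gene, rmap in maps.items():
            for r in rmap.regions:
                lines.append(f"{gene}\t{r.label}\t{r.start}\t{r.end}\t{r.kind.value}")
        Path(path).write_text("\n".join(lines) + "\n")
    return maps


def write_dataset(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic dataset (catalogue, energies, region map,
    two MSAs, variant fold changes) into ``outdir``."""
    from .catalog import parse_mutations  # local import avoids cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["catalog"] = gen_catalog(config, outdir / "catalog.tsv")
    records = parse_mutations(paths["catalog"])
    paths["energies"] = gen_energy_table(config, records, outdir / "energies.tsv")
    gen_region_maps(("KRAS", "PTPN11"), seed=config.seed, path=outdir / "regions.tsv")
    paths["regions"] = outdir / "regions.tsv"
    for gene in ("KRAS", "PTPN11"):
        paths[f"msa_{gene}"] = gen_msa(config, gene, outdir / f"msa_{gene}.fasta")
    fold_changes = gen_fold_changes(config)
    variants = {
        fc.name: {
            "gef": fc.gef,
            "gap": fc.gap,
            "intrinsic_exchange": fc.intrinsic_exchange,
            "intrinsic_hydrolysis": fc.intrinsic_hydrolysis,
            "kd_eff": fc.kd_eff,
        }
        for fc in fold_changes
        if not fc.is_wild_type
    }
    (outdir / "variants.yaml").write_text(yaml.safe_dump({"variants": variants}, sort_keys=True))
    paths["variants"] = outdir / "variants.yaml"
    return paths
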