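"""Synthetic three-cohort whole-exome dataset generator.

Emulates the statistical structure the downstream analysis assumes: three
cohorts (cases, epilepsy controls, disease controls), a rare-variant site
frequency spectrum, per-variant deleteriousness scores, capture-kit
structured missingness, and configurable planted case-burden effects
(excess variant count, excess deleteriousness, case-exclusive genes).

Scale is deliberately reduced relative to a real exome study (a few
thousand variants rather than tens of thousands); gene and variant counts
are chosen for test power, not realism.  All stochastic draws flow from a
single integer seed, so outputs are byte-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    CohortManifest,
    GenotypeMatrix,
    VariantRecord,
    write_annotations,
    write_manifest,
    write_vcf,
)

_SYNDROMES = ["DS", "focal_symptomatic", "focal_unknown", "GGE", "unclassified"]
_SYNDROME_P = [0.34, 0.28, 0.11, 0.14, 0.13]

_FUNC_CLASSES = [
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "canonical_splice",
    "synonymous",
    "noncoding",
]
_FUNC_P = [0.55, 0.05, 0.05, 0.05, 0.05, 0.18, 0.07]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    With ``effect_count = 1``, ``effect_score = 0`` and no exclusive genes,
    the three groups are exchangeable: genotypes are drawn from the same
    per-variant frequencies and the default kit mixture is identical across
    cohorts, so any apparent group difference is sampling noise.

    The minor-allele-frequency spectrum is Beta(0.2, 200) truncated to
    (0, maf_max], a heavy rare tail with every site passing the 0.5% rarity
    filter by construction.  Scaled deleteriousness scores are a mixture of
    Uniform(0, 15) and Uniform(15, 40) so that the score >= 15 gene-stage
    filter has both branches populated.
    """

    n_case: int = 18
    n_epi_ctrl: int = 87
    n_dis_ctrl: int = 1479
    n_genes: int = 150
    mean_variants_per_gene: float = 70.0
    maf_beta: tuple[float, float] = (0.2, 200.0)
    maf_max: float = 0.005
    cadd_high_weight: float = 0.3
    cadd_low_range: tuple[float, float] = (0.0, 15.0)
    cadd_high_range: tuple[float, float] = (15.0, 40.0)
    # Capture kits: each kit covers a random subset of variants; covered
    # sites are callable with prob kit_call_prob, uncovered with
    # kit_dropout_call_prob.  kit_mixtures gives per-cohort assignment
    # probabilities (rows: case, epilepsy_control, disease_control).
    kit_coverages: tuple[float, ...] = (0.98, 0.92, 0.85)
    kit_call_prob: float = 0.995
    kit_dropout_call_prob: float = 0.05
    kit_mixtures: tuple[tuple[float, ...], ...] | None = None
    effect_count: float = 1.0
    effect_score: float = 0.0
    exclusive_genes: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_epi_ctrl, self.n_dis_ctrl) < 1:
            raise ConfigError("cohort sizes must be positive")
        if self.effect_count < 1 or self.effect_score < 0:
            raise ConfigError("effect_count >= 1 and effect_score >= 0 required")
        if not 0 < self.maf_max <= 0.5:
            raise ConfigError("maf_max must lie in (0, 0.5]")
        mix = self.kit_mixtures
        if mix is not None:
            if len(mix) != 3 or any(len(m) != len(self.kit_coverages) for m in mix):
                raise ConfigError(
                    "kit_mixtures must be 3 rows (one per cohort) x n_kits"
                )
            for m in mix:
                if abs(sum(m) - 1.0) > 1e-9 or min(m) < 0:
                    raise ConfigError("kit mixture rows must be probabilities")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_epi_ctrl + self.n_dis_ctrl

    def mixtures(self) -> np.ndarray:
        if self.kit_mixtures is not None:
            return np.asarray(self.kit_mixtures, dtype=float)
        # identical mixture for every cohort: exchangeable missingness
        k = len(self.kit_coverages)
        base = np.full(k, 1.0 / k)
        return np.tile(base, (3, 1))


def _truncated_beta(rng: np.random.Generator, a: float, b: float, hi: float,
                    size: int) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    bad = (out > hi) | (out <= 0)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out > hi) | (out <= 0)
    return out


def _draw_variants(cfg: SimConfig, rng: np.random.Generator):
    """Gene assignment, positions/alleles, MAFs and annotations."""
    per_gene = 1 + rng.poisson(max(cfg.mean_variants_per_gene - 1, 0.0),
                               size=cfg.n_genes)
    genes = np.repeat([f"GENE{i:04d}" for i in range(cfg.n_genes)], per_gene)
    n_var = int(per_gene.sum())

    maf = _truncated_beta(rng, *cfg.maf_beta, cfg.maf_max, n_var)
    high = rng.random(n_var) < cfg.cadd_high_weight
    cadd = np.where(
        high,
        rng.uniform(*cfg.cadd_high_range, size=n_var),
        rng.uniform(*cfg.cadd_low_range, size=n_var),
    )
    func = rng.choice(_FUNC_CLASSES, size=n_var, p=_FUNC_P)

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_var)
    alt_i = (ref_i + rng.integers(1, 4, size=n_var)) % 4

    chroms = (np.arange(n_var) % 22) + 1
    pos = 1000 + np.arange(n_var) * 137  # unique, strictly increasing per chrom
    records: dict[str, VariantRecord] = {}
    keys: list[str] = []
    for i in range(n_var):
        rec = VariantRecord(
            chrom=str(chroms[i]),
            pos=int(pos[i]),
            ref=bases[ref_i[i]],
            alt=bases[alt_i[i]],
            gene=str(genes[i]),
            func_class=str(func[i]),
            ref_maf=float(maf[i]),
            cadd_raw=float(cadd[i] / 10.0),  # raw score on its native scale
            cadd_scaled=float(cadd[i]),
        )
        records[rec.key] = rec
        keys.append(rec.key)
    return keys, records, maf


def _draw_genotypes(cfg: SimConfig, rng: np.random.Generator, maf: np.ndarray,
                    groups: np.ndarray) -> np.ndarray:
    n_var = len(maf)
    geno = rng.binomial(2, maf[None, :], size=(cfg.n_samples, n_var))
    if cfg.effect_count > 1:
        p_case = np.minimum(maf * cfg.effect_count, 0.5)
        case_rows = np.where(groups == "case")[0]
        geno[case_rows] = rng.binomial(
            2, p_case[None, :], size=(len(case_rows), n_var)
        )
    return geno.astype(np.int8)


def _apply_kits(cfg: SimConfig, rng: np.random.Generator, geno: np.ndarray,
                groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mask genotypes to MISSING per capture-kit callable probabilities."""
    n_var = geno.shape[1]
    n_kits = len(cfg.kit_coverages)
    covered = np.stack(
        [rng.random(n_var) < c for c in cfg.kit_coverages]
    )  # kits x variants
    call_p = np.where(covered, cfg.kit_call_prob, cfg.kit_dropout_call_prob)

    mix = cfg.mixtures()
    cohort_row = {"case": 0, "epilepsy_control": 1, "disease_control": 2}
    kit_of = np.empty(len(groups), dtype=int)
    for g, row in cohort_row.items():
        idx = np.where(groups == g)[0]
        kit_of[idx] = rng.choice(n_kits, size=len(idx), p=mix[row])

    called = rng.random(geno.shape) < call_p[kit_of, :]
    geno = np.where(called, geno, MISSING).astype(np.int8)
    return geno, kit_of


def _simulate_manifest(cfg: SimConfig, rng: np.random.Generator,
                       samples: list[str], groups: np.ndarray) -> CohortManifest:
    n = len(samples)
    is_epi = groups != "disease_control"
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age_first = np.round(np.exp(rng.normal(np.log(3.0), 1.0, size=n)), 1)
    duration = np.round(np.clip(rng.normal(28, 15, size=n), 1, 70), 1)
    age_last = np.round(age_first + duration, 1)
    syndrome = rng.choice(_SYNDROMES, size=n, p=_SYNDROME_P)
    n_aeds = rng.poisson(8, size=n)

    def tristate(p_yes: float) -> np.ndarray:
        u = rng.random(n)
        out = np.where(u < p_yes, "yes", "no").astype(object)
        out[rng.random(n) < 0.05] = "."
        return out

    df = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "sex": sex,
            "age_last_followup": age_last,
            "age_first_seizure": np.where(is_epi, age_first, np.nan),
            "epilepsy_duration": np.where(is_epi, duration, np.nan),
            "syndrome": np.where(is_epi, syndrome, "."),
            "intellectual_disability": tristate(0.47),
            "lives_alone": tristate(0.08),
            "convulsive_seizures_12m": tristate(0.45),
            "nocturnal_seizures_12m": tristate(0.40),
            "n_aeds": pd.array(np.where(is_epi, n_aeds, -1), dtype="Int64"),
        }
    )
    df.loc[~is_epi, "n_aeds"] = pd.NA
    for col in ("intellectual_disability", "lives_alone",
                "convulsive_seizures_12m", "nocturnal_seizures_12m"):
        df.loc[~is_epi, col] = "."
    return CohortManifest(table=df)


def plant_exclusive_gene(
    matrix: GenotypeMatrix,
    annotations: dict[str, VariantRecord],
    gene: str,
    n_case_carriers: int,
    n_ctrl_carriers: int,
    rng: np.random.Generator | None = None,
    cadd_scaled: float = 28.0,
    allow_new_gene: bool = True,
) -> tuple[GenotypeMatrix, dict[str, VariantRecord]]:
    """Seed a gene with group-exclusive heterozygous singleton variants.

    Adds one new fully-callable variant per carrier: ``n_case_carriers``
    variants each carried by exactly one case, and ``n_ctrl_carriers``
    carried by exactly one disease control, so the planted alleles are
    exclusive to their group.  Planted variants are missense with a scaled
    deleteriousness score >= 15 and a reference MAF of 1e-4, so they pass
    every gene-stage filter.
    """
    rng = rng or np.random.default_rng()
    known_genes = {r.gene for r in annotations.values()}
    if gene not in known_genes and not allow_new_gene:
        raise ValueError(f"gene {gene!r} not present in annotations")
    if cadd_scaled < 15:
        raise ValueError("planted variants must have scaled score >= 15")

    case_idx = np.where(matrix.groups == "case")[0]
    ctrl_idx = np.where(matrix.groups == "disease_control")[0]
    if n_case_carriers > len(case_idx) or n_ctrl_carriers > len(ctrl_idx):
        raise ValueError("carrier counts exceed cohort sizes")

    carriers = list(rng.choice(case_idx, size=n_case_carriers, replace=False))
    carriers += list(rng.choice(ctrl_idx, size=n_ctrl_carriers, replace=False))

    max_pos = 0
    for r in annotations.values():
        if r.chrom == "23":
            max_pos = max(max_pos, r.pos)
    annotations = dict(annotations)
    new_cols = []
    new_keys = []
    for j, s_idx in enumerate(carriers):
        rec = VariantRecord(
            chrom="23",
            pos=max_pos + 1 + j,
            ref="A",
            alt="T",
            gene=gene,
            func_class="missense",
            ref_maf=1e-4,
            cadd_raw=cadd_scaled / 10.0,
            cadd_scaled=cadd_scaled,
        )
        if rec.key in annotations:
            raise ValueError(f"planted key collision: {rec.key}")
        annotations[rec.key] = rec
        col = np.zeros(matrix.n_samples, dtype=np.int8)
        col[s_idx] = 1
        new_cols.append(col)
        new_keys.append(rec.key)

    geno = (
        np.concatenate([matrix.geno, np.stack(new_cols, axis=1)], axis=1)
        if new_cols
        else matrix.geno
    )
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        variants=list(matrix.variants) + new_keys,
        geno=geno,
        groups=matrix.groups.copy(),
    )
    return out, annotations


def simulate(cfg: SimConfig):
    """Draw one synthetic cohort in memory.

    Returns ``(matrix, annotations, manifest)``.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = (
        [f"SUDEP{i:03d}" for i in range(cfg.n_case)]
        + [f"EPI{i:03d}" for i in range(cfg.n_epi_ctrl)]
        + [f"CTRL{i:04d}" for i in range(cfg.n_dis_ctrl)]
    )
    groups = np.array(
        ["case"] * cfg.n_case
        + ["epilepsy_control"] * cfg.n_epi_ctrl
        + ["disease_control"] * cfg.n_dis_ctrl,
        dtype=object,
    )

    keys, records, maf = _draw_variants(cfg, rng)
    geno = _draw_genotypes(cfg, rng, maf, groups)
    geno, _ = _apply_kits(cfg, rng, geno, groups)

    if cfg.effect_score > 0:
        # deleteriousness shift on every variant carried by at least one
        # case; with a rare spectrum these are mostly case-exclusive sites
        case_rows = groups == "case"
        carried = (geno[case_rows] > 0).any(axis=0)
        for k, hit in zip(keys, carried):
            if hit:
                r = records[k]
                records[k] = VariantRecord(
                    chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                    gene=r.gene, func_class=r.func_class, ref_maf=r.ref_maf,
                    cadd_raw=r.cadd_raw + cfg.effect_score / 10.0,
                    cadd_scaled=r.cadd_scaled + cfg.effect_score,
                )

    matrix = GenotypeMatrix(samples=samples, variants=keys, geno=geno,
                            groups=groups)
    for gene, n_case_c, n_ctrl_c in cfg.exclusive_genes:
        matrix, records = plant_exclusive_gene(
            matrix, records, gene, n_case_c, n_ctrl_c, rng=rng
        )
    manifest = _simulate_manifest(cfg, rng, matrix.samples, matrix.groups)
    return matrix, records, manifest


def simulate_cohort(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write ``cohort.vcf``, ``annotations.tsv``, ``manifest.tsv``."""
    matrix, records, manifest = simulate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    write_vcf(matrix, paths["vcf"])
    write_annotations(records, paths["annotations"])
    write_manifest(manifest, paths["manifest"])
    return paths
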