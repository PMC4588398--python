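"""File formats and the in-memory data model.

The pipeline consumes three plain-text inputs — a multi-sample VCF with GT
fields, a tab-separated variant annotation table and a tab-separated sample
manifest — and emits tab-separated result tables.  Genotypes are held as a
dense samples × variants matrix of small integers; a missing genotype is a
distinct code (``MISSING = -1``) and is never conflated with homozygous
reference, mirroring the joint-calling convention that makes the two
distinguishable in the first place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING: int = -1

GROUPS = ("case", "epilepsy_control", "disease_control")

FUNC_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "canonical_splice",
        "synonymous",
        "noncoding",
    }
)

ANNOTATION_COLUMNS = [
    "key",
    "gene",
    "func_class",
    "ref_maf",
    "cadd_raw",
    "cadd_scaled",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "sex",
    "age_last_followup",
    "age_first_seizure",
    "epilepsy_duration",
    "syndrome",
    "intellectual_disability",
    "lives_alone",
    "convulsive_seizures_12m",
    "nocturnal_seizures_12m",
    "n_aeds",
]

TRISTATE_COLUMNS = [
    "intellectual_disability",
    "lives_alone",
    "convulsive_seizures_12m",
    "nocturnal_seizures_12m",
]

UNKNOWN = "."


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalise an allele pair by trimming shared suffix then prefix.

    Keeps at least one base on each side; the position is advanced by the
    number of prefix bases removed.  This makes the ``chrom:pos:ref:alt``
    key unambiguous for the annotation join.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantRecord:
    """One annotated, biallelic exonic variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    ref_maf: float
    cadd_raw: float
    cadd_scaled: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {self.func_class!r}")
        if not 0.0 <= self.ref_maf <= 0.5:
            raise ValueError(
                f"ref_maf must lie in [0, 0.5] (minor-allele convention), "
                f"got {self.ref_maf}"
            )
        if self.cadd_scaled < 0:
            raise ValueError(f"cadd_scaled must be >= 0, got {self.cadd_scaled}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples × variants genotype codes with per-sample group labels.

    ``geno[s, v]`` counts non-reference alleles (0, 1 or 2) or is
    ``MISSING``.  Phase is discarded on read.
    """

    samples: list[str]
    variants: list[str]
    geno: np.ndarray
    groups: np.ndarray  # str array aligned with samples

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.geno.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.groups) != len(self.samples):
            raise ValueError("groups must align with samples")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return self.groups == group

    def variant_index(self, key: str) -> int:
        try:
            return self.variants.index(key)
        except ValueError:
            raise KeyError(f"variant {key!r} not in matrix") from None

    def subset_variants(self, keys) -> "GenotypeMatrix":
        idx = [self.variant_index(k) for k in keys]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            geno=self.geno[:, idx].copy(),
            groups=self.groups.copy(),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=[s for s, m in zip(self.samples, mask) if m],
            variants=list(self.variants),
            geno=self.geno[mask].copy(),
            groups=self.groups[mask].copy(),
        )


@dataclass
class CohortManifest:
    """Per-sample group labels and clinical covariates (Table-1 style)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample id(s): {sorted(set(dup))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_code(gt: tuple, alt_index: int) -> int:
    """Count copies of allele ``alt_index`` in a GT tuple; half-calls -> MISSING."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return sum(1 for a in gt if a == alt_index)


def read_vcf(path, manifest: CohortManifest | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT subfield) into a :class:`GenotypeMatrix`.

    Multi-allelic rows are decomposed into one biallelic record per
    alternate allele; the per-sample code for each record counts copies of
    that allele.  Any genotype containing a no-call allele (``./.``,
    ``0/.``) maps to ``MISSING`` for every decomposed record of the site.

    When a manifest is given, sample group labels are taken from it and the
    VCF's sample set must be a subset of the manifest's; otherwise all
    samples are labelled ``disease_control`` as a neutral placeholder.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if manifest is not None:
        known = manifest.group_of()
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise FormatError(
                f"sample(s) in VCF absent from manifest: {unknown}"
            )
        groups = np.array([known[s] for s in samples], dtype=object)
    else:
        groups = np.array(["disease_control"] * len(samples), dtype=object)

    keys: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        alts = rec.alts or ()
        gts = [rec.samples[s].get("GT") for s in samples]
        for ai, alt in enumerate(alts, start=1):
            if alt is None or alt in {"*", "<NON_REF>"}:
                continue
            pos, ref, alt_t = trim_alleles(rec.pos, rec.ref, alt)
            keys.append(f"{rec.chrom}:{pos}:{ref}:{alt_t}")
            columns.append(
                np.array([_genotype_code(gt, ai) for gt in gts], dtype=np.int8)
            )
    vcf.close()

    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=keys, geno=geno, groups=groups)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only) for a genotype matrix."""
    def gt_str(code: int) -> str:
        return {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(code), "./.")

    recs = []
    for key in matrix.variants:
        chrom, pos, ref, alt = key.split(":")
        recs.append((chrom, int(pos), ref, alt))

    # matrix order is preserved so that write -> read round-trips exactly
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = []
        for chrom, *_ in recs:
            if chrom not in contigs:
                contigs.append(chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, (chrom, pos, ref, alt) in enumerate(recs):
            gts = "\t".join(gt_str(c) for c in matrix.geno[:, i])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotations(path) -> dict[str, VariantRecord]:
    """Read the variant annotation TSV into a key -> record map."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "gene": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    dup = df.loc[df["key"].duplicated(), "key"]
    if len(dup):
        raise FormatError(f"duplicate annotation key(s): {sorted(set(dup))}")
    out: dict[str, VariantRecord] = {}
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = str(row.key).split(":")
        out[row.key] = VariantRecord(
            chrom=chrom,
            pos=int(pos),
            ref=ref,
            alt=alt,
            gene=row.gene,
            func_class=row.func_class,
            ref_maf=float(row.ref_maf),
            cadd_raw=float(row.cadd_raw),
            cadd_scaled=float(row.cadd_scaled),
        )
    return out


def write_annotations(records: dict[str, VariantRecord], path) -> None:
    rows = [
        {
            "key": r.key,
            "gene": r.gene,
            "func_class": r.func_class,
            "ref_maf": r.ref_maf,
            "cadd_raw": r.cadd_raw,
            "cadd_scaled": r.cadd_scaled,
        }
        for r in records.values()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def reconcile_annotations(
    matrix: GenotypeMatrix, annotations: dict[str, VariantRecord]
) -> tuple[GenotypeMatrix, int]:
    """Drop matrix variants without an annotation; return (matrix, n_dropped)."""
    keep = [k for k in matrix.variants if k in annotations]
    n_dropped = matrix.n_variants - len(keep)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} variant(s) without annotation excluded", stacklevel=2
        )
        matrix = matrix.subset_variants(keep)
    return matrix, n_dropped


# ---------------------------------------------------------------------------
# Manifest and result tables
# ---------------------------------------------------------------------------

def read_manifest(path) -> CohortManifest:
    """Read the sample manifest TSV; '.' marks unknown tri-state entries."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    for col in ("age_last_followup", "age_first_seizure", "epilepsy_duration"):
        df[col] = pd.to_numeric(df[col].replace(UNKNOWN, np.nan))
    df["n_aeds"] = pd.to_numeric(df["n_aeds"].replace(UNKNOWN, np.nan)).astype(
        "Int64"
    )
    return CohortManifest(table=df)


def write_manifest(manifest: CohortManifest, path) -> None:
    df = manifest.table.copy()
    for col in df.columns:
        df[col] = df[col].astype(object)
    df = df.where(pd.notna(df), UNKNOWN)
    df.to_csv(path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write each result table as ``<name>.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p
    return written
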