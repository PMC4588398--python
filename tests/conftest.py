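"""Shared fixtures: hand-written genotype matrices, a small simulated
cohort, and the constructed batch-effect dataset for the threshold sweep."""

from __future__ import annotations

import numpy as np
import pytest

from sudep_burden.io_formats import MISSING, GenotypeMatrix, VariantRecord
from sudep_burden.synthetic_cohort import SimConfig, simulate


def make_record(key, gene="G1", func_class="missense", ref_maf=0.001,
                cadd_scaled=20.0):
    chrom, pos, ref, alt = key.split(":")
    return VariantRecord(
        chrom=chrom, pos=int(pos), ref=ref, alt=alt, gene=gene,
        func_class=func_class, ref_maf=ref_maf, cadd_raw=cadd_scaled / 10.0,
        cadd_scaled=cadd_scaled,
    )


@pytest.fixture
def hand_matrix():
    """5 samples x 4 variants with known genotypes and annotations.

    Burden scores are hand-computable: cadd_scaled = 12.3, 20.0, 5.0, 30.0.
    """
    keys = ["1:100:A:G", "1:200:C:T", "2:300:G:A", "2:400:T:C"]
    ann = {
        keys[0]: make_record(keys[0], gene="GA", cadd_scaled=12.3),
        keys[1]: make_record(keys[1], gene="GA", cadd_scaled=20.0),
        keys[2]: make_record(keys[2], gene="GB", cadd_scaled=5.0),
        keys[3]: make_record(keys[3], gene="GB", cadd_scaled=30.0),
    }
    geno = np.array(
        [
            [1, 1, 0, 0],        # carries v0+v1 -> 32.3, count 2
            [0, 0, 2, 0],        # hom v2 -> 5.0, count 1
            [MISSING, MISSING, MISSING, MISSING],  # all missing -> 0, 0
            [0, 0, 0, 1],        # v3 -> 30.0, count 1
            [2, 0, 1, 1],        # v0 hom + v2 + v3 -> 47.3, count 3
        ],
        dtype=np.int8,
    )
    groups = np.array(
        ["case", "case", "epilepsy_control", "disease_control",
         "disease_control"], dtype=object,
    )
    matrix = GenotypeMatrix(
        samples=[f"S{i}" for i in range(5)], variants=keys, geno=geno,
        groups=groups,
    )
    return matrix, ann


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort at reduced scale, shared across tests."""
    cfg = SimConfig(seed=42, n_genes=40, mean_variants_per_gene=10)
    return simulate(cfg)


def build_batch_effect_dataset(seed=0, n_case=18, n_epi=87, n_dis=195,
                               n_full=1000, n_random=500, n_batch=1500,
                               sparse_kit_fraction=0.25):
    """Three variant tiers with distinct sequenced fractions.

    * full tier: called everywhere (survives every threshold);
    * random tier: ~86% called uniformly at random (sequenced fraction in
      (0.8, 0.9], dropped only at threshold 0.9);
    * batch tier: dropped almost entirely for the quarter of each cohort
      assigned to a sparse capture kit (sequenced fraction ~0.76, so it
      enters the selection at thresholds <= 0.7 and inflates the spread of
      burden scores between kit groups).
    """
    rng = np.random.default_rng(seed)
    n = n_case + n_epi + n_dis
    groups = np.array(
        ["case"] * n_case + ["epilepsy_control"] * n_epi
        + ["disease_control"] * n_dis, dtype=object,
    )
    n_var = n_full + n_random + n_batch
    geno = rng.binomial(2, 0.005, size=(n, n_var)).astype(np.int8)

    sparse_kit = np.zeros(n, dtype=bool)
    for g in ("case", "epilepsy_control", "disease_control"):
        idx = np.where(groups == g)[0]
        take = int(round(sparse_kit_fraction * len(idx)))
        sparse_kit[rng.choice(idx, size=take, replace=False)] = True

    called = np.ones((n, n_var), dtype=bool)
    called[:, n_full:n_full + n_random] = rng.random((n, n_random)) < 0.86
    p_batch = np.where(sparse_kit[:, None], 0.05, 0.995)
    called[:, n_full + n_random:] = rng.random((n, n_batch)) < p_batch
    geno = np.where(called, geno, MISSING).astype(np.int8)

    keys, ann = [], {}
    for j in range(n_var):
        rec = make_record(
            f"1:{j + 1}:A:G", gene=f"G{j // 10}", ref_maf=0.005,
            cadd_scaled=float(rng.uniform(10, 20)),
        )
        keys.append(rec.key)
        ann[rec.key] = rec
    matrix = GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)], variants=keys, geno=geno,
        groups=groups,
    )
    return matrix, ann
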