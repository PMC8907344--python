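import math

import numpy as np
import pytest

from acetylome import (
    DEFAULT_DESIGN,
    ImputationParams,
    SimConfig,
    ValidationError,
    compute_changes,
    generate_experiment,
    impute,
    pair_filter,
    population_stats,
)
from acetylome.preprocess import BOTH_MISSING, PROTEIN_UNQUANTIFIED


def test_impute_without_missing_is_identity(make_site):
    sites = [make_site(values=(2.0, 4.0, 8.0, 16.0))]
    out = impute(sites, ImputationParams(seed=1), DEFAULT_DESIGN)
    assert out[0].intensity == sites[0].intensity
    assert not any(out[0].imputed.values())


def test_impute_draws_are_bounded_and_flagged(make_site):
    rng = np.random.default_rng(3)
    sites = []
    for i in range(500):
        values = [float(2.0 ** rng.normal(25.0, 2.0)) for _ in range(4)]
        values[0] = None  # s3 missing, partner s1 observed -> eligible
        sites.append(make_site(accession=f"P{i}", values=values))
    mu, sigma = population_stats(sites)
    out = impute(sites, ImputationParams(seed=9), DEFAULT_DESIGN)
    draws = [math.log2(r.intensity["s3"]) for r in out]
    assert all(r.imputed["s3"] and not r.imputed["s1"] for r in out)
    assert sum(sum(r.imputed.values()) for r in out) == 500  # flags == eligible cells
    lo, hi = mu - 2.1 * sigma, mu - 1.5 * sigma
    assert min(draws) >= lo and max(draws) <= hi
    # observed values untouched
    for before, after in zip(sites, out):
        for s in ("s1", "s7", "s5"):
            assert before.intensity[s] == after.intensity[s]


def test_impute_respects_pair_rule(make_site):
    # s3 and s1 (knockdown arm) both missing: ineligible, stays missing
    sites = [
        make_site(accession="P0", values=(None, None, 8.0, 16.0)),
        make_site(accession="P1", values=(4.0, 4.0, 4.0, 4.0)),
    ]
    out = impute(sites, ImputationParams(seed=1), DEFAULT_DESIGN)
    assert out[0].intensity["s3"] is None and out[0].intensity["s1"] is None
    assert not any(out[0].imputed.values())


def test_impute_is_reproducible_from_seed(make_site):
    sites = [make_site(accession=f"P{i}", values=(None, 2.0**24, 2.0**25, 2.0**26)) for i in range(10)]
    a = impute(sites, ImputationParams(seed=4), DEFAULT_DESIGN)
    b = impute(sites, ImputationParams(seed=4), DEFAULT_DESIGN)
    assert [r.intensity for r in a] == [r.intensity for r in b]


def test_impute_degenerate_populations_raise(make_site):
    with pytest.raises(ValidationError):
        impute([make_site(values=(None, None, None, None))], ImputationParams())
    with pytest.raises(ValidationError):  # sigma == 0
        impute(
            [make_site(values=(8.0, 8.0, 8.0, None))],
            ImputationParams(),
            DEFAULT_DESIGN,
        )


def test_imputation_params_validation():
    with pytest.raises(ValidationError):
        ImputationParams(downshift=0.0)
    with pytest.raises(ValidationError):
        ImputationParams(halfwidth=-0.1)


@pytest.mark.parametrize(
    "acetyl_imputed, protein_values, expected_keep, expected_reason",
    [
        ((False, False), (1.0, 1.0, 1.0, 1.0), True, None),
        ((True, True), (1.0, 1.0, 1.0, 1.0), False, BOTH_MISSING),
        ((False, False), (None, None, 1.0, 1.0), False, PROTEIN_UNQUANTIFIED),
    ],
)
def test_pair_filter_rules(
    make_site, make_protein, acetyl_imputed, protein_values, expected_keep, expected_reason
):
    site = make_site(values=(2.0, 4.0, 8.0, 16.0))
    site.imputed["s3"], site.imputed["s1"] = acetyl_imputed
    protein = make_protein(values=protein_values)
    keep, reason = pair_filter(site, protein, DEFAULT_DESIGN.knockdown)
    assert keep is expected_keep
    assert reason == expected_reason


def test_pair_filter_protein_absent(make_site):
    keep, reason = pair_filter(make_site(), None, DEFAULT_DESIGN.knockdown)
    assert not keep and reason == PROTEIN_UNQUANTIFIED


def test_unquantified_protein_excludes_all_its_peptides(make_site, make_protein):
    sites = [make_site(accession="P1", peptide=f"AAK{'A' * i}", values=(2, 1, 1, 1)) for i in range(3)]
    proteins = [make_protein(accession="P1", values=(None, None, 2.0, 2.0))]
    changes = compute_changes(sites, proteins, DEFAULT_DESIGN)
    kd = changes[changes["arm"] == "knockdown"]
    assert kd["excluded"].all()
    assert (kd["reason"] == PROTEIN_UNQUANTIFIED).all()


def test_compute_changes_arithmetic(make_site, make_protein):
    # site ratio 3.0 with protein ratio 2.0 -> normalized 1.5
    sites = [make_site(values=(3.0, 1.0, 1.0, 1.0))]
    proteins = [make_protein(values=(2.0, 1.0, 1.0, 1.0))]
    changes = compute_changes(sites, proteins, DEFAULT_DESIGN)
    kd = changes[changes["arm"] == "knockdown"].iloc[0]
    assert kd["raw_ratio"] == pytest.approx(3.0)
    assert kd["protein_ratio"] == pytest.approx(2.0)
    assert kd["normalized_ratio"] == pytest.approx(1.5)
    # protein ratio 1.0 in the other arm -> normalized equals raw
    oe = changes[changes["arm"] == "overexpression"].iloc[0]
    assert oe["normalized_ratio"] == pytest.approx(oe["raw_ratio"])


def test_normalized_ratio_identity_on_retained_pairs(make_site, make_protein):
    rng = np.random.default_rng(11)
    sites, proteins = [], []
    for i in range(50):
        sites.append(
            make_site(accession=f"P{i}", values=tuple(2.0 ** rng.normal(25, 2, 4)))
        )
        proteins.append(
            make_protein(accession=f"P{i}", values=tuple(2.0 ** rng.normal(25, 1, 4)))
        )
    changes = compute_changes(sites, proteins, DEFAULT_DESIGN)
    kept = changes[~changes["excluded"]]
    assert len(kept) == 100
    np.testing.assert_allclose(
        kept["normalized_ratio"], kept["raw_ratio"] / kept["protein_ratio"], rtol=1e-12
    )


def test_normalization_scale_invariance(make_site, make_protein):
    rng = np.random.default_rng(12)
    sites = [make_site(accession=f"P{i}", values=tuple(2.0 ** rng.normal(25, 2, 4))) for i in range(20)]
    proteins = [make_protein(accession=f"P{i}", values=tuple(2.0 ** rng.normal(25, 1, 4))) for i in range(20)]
    base = compute_changes(sites, proteins, DEFAULT_DESIGN)

    c = 7.3
    scaled_sites = [
        make_site(
            accession=s.protein_accession,
            values=tuple(
                v * c if sample == "s3" else v for sample, v in s.intensity.items()
            ),
        )
        for s in sites
    ]
    scaled_proteins = [
        make_protein(
            accession=p.protein_accession,
            values=tuple(
                v * c if sample == "s3" else v for sample, v in p.lfq.items()
            ),
        )
        for p in proteins
    ]
    # same factor on both tables: normalized ratios unchanged
    both = compute_changes(scaled_sites, scaled_proteins, DEFAULT_DESIGN)
    np.testing.assert_allclose(
        both["normalized_ratio"], base["normalized_ratio"], rtol=1e-9
    )
    # factor on the acetyl table only: knockdown normalized ratios scale by c
    acetyl_only = compute_changes(scaled_sites, proteins, DEFAULT_DESIGN)
    kd_new = acetyl_only[acetyl_only["arm"] == "knockdown"]["normalized_ratio"]
    kd_old = base[base["arm"] == "knockdown"]["normalized_ratio"]
    np.testing.assert_allclose(kd_new.to_numpy(), c * kd_old.to_numpy(), rtol=1e-9)


def test_noise_free_planted_effects_normalize_exactly():
    config = SimConfig(
        n_proteins=150,
        frac_direct=0.1,
        frac_indirect=0.1,
        effect_log2=1.0,
        noise_sd=0.0,
        protein_change_sd=0.5,
        missingness=(21.0, 0.0),
        seed=8,
    )
    experiment = generate_experiment(config)
    changes = compute_changes(experiment.sites, experiment.proteins, DEFAULT_DESIGN)
    merged = changes.merge(experiment.truth[["record", "site_class"]], on="record")
    direct = merged[merged["site_class"] == "direct"]
    assert len(direct) > 0
    kd = direct[direct["arm"] == "knockdown"]["normalized_ratio"]
    oe = direct[direct["arm"] == "overexpression"]["normalized_ratio"]
    # protein-level shifts (sd 0.5) cancel exactly under normalization
    np.testing.assert_allclose(kd, 2.0, rtol=1e-9)
    np.testing.assert_allclose(oe, 0.5, rtol=1e-9)
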