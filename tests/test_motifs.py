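import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylome import (
    BackgroundModel,
    ValidationError,
    binomial_p,
    motifx_extract,
    planted_motif_windows,
    residue_heatmap,
    trim_windows,
)
from acetylome.motifs import AMINO_ACIDS, Motif, MotifStep


def exact_binomial_tail(n: int, k: int, p0: Fraction) -> Fraction:
    """Independent brute-force upper tail by direct summation."""
    return sum(
        Fraction(math.comb(n, i)) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
    )


def exact_fisher_two_sided(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration with exact fractions."""
    a_total = k_fg + k_bg
    total = n_fg + n_bg

    def pmf(a: int) -> Fraction:
        return Fraction(
            math.comb(a_total, a) * math.comb(total - a_total, n_fg - a),
            math.comb(total, n_fg),
        )

    observed = pmf(k_fg)
    lo = max(0, a_total - n_bg)
    hi = min(a_total, n_fg)
    # include all tables at most as probable as the observed one
    return float(sum(pmf(a) for a in range(lo, hi + 1) if pmf(a) <= observed))


def test_binomial_p_trivial_cases():
    assert binomial_p(10, 0, 0.3) == 1.0
    assert binomial_p(10, 7, 1.0) == 1.0
    with pytest.raises(ValidationError):
        binomial_p(5, 6, 0.1)
    with pytest.raises(ValidationError):
        binomial_p(5, 2, 1.5)


def test_binomial_p_matches_direct_summation_to_12_digits():
    expected = float(exact_binomial_tail(10, 2, Fraction(1, 10)))
    assert binomial_p(10, 2, 0.1) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 200),
    k=st.integers(0, 200),
    p0=st.floats(0.01, 0.99),
    delta=st.floats(0.0, 0.3),
)
def test_binomial_p_monotonicity(n, k, p0, delta):
    k = min(k, n)
    assert binomial_p(n, k, min(p0 + delta, 1.0)) >= binomial_p(n, k, p0)
    if k < n:
        assert binomial_p(n, k + 1, p0) <= binomial_p(n, k, p0)


def test_motifx_recovers_planted_motif():
    foreground, proteome = planted_motif_windows(
        200, 20_000, motif=(5, "K"), enrichment=0.6, seed=0
    )
    background = BackgroundModel.from_proteome(proteome, half_width=5)
    motifs = motifx_extract(foreground, background)
    assert [m.pattern for m in motifs] == ["K(ac)xxxxK"]
    assert motifs[0].n_matching >= 100
    assert all(p < 0.001 for p in motifs[0].p_values)


def test_motifx_occurrence_floor():
    foreground, proteome = planted_motif_windows(
        11, 2000, motif=(5, "K"), enrichment=1.0, seed=1
    )
    background = BackgroundModel.from_proteome(proteome, half_width=5)
    assert motifx_extract(foreground, background, min_occurrences=12) == []


def test_motifx_foreground_identical_to_background_sample_is_null():
    # when the foreground IS the background sample the enrichment test is
    # self-referential and can never reach significance
    for seed in range(5):
        windows, _ = planted_motif_windows(200, 10, motif=(1, "A"), enrichment=0.0, seed=seed)
        assert motifx_extract(windows, windows) == []


def test_motifx_null_calibration_against_attained_level_oracle():
    """Foreground drawn at background frequencies: the spurious-motif rate
    equals the summed attained significance levels of the candidate tests.

    At the extraction threshold 1e-3 a 200-window null foreground has
    ~0.09 expected false fixes (the analytic attained-level sum over all
    200 candidate (position, residue) tests), so a spurious motif appears
    in roughly one seed in eleven; at the stringent 1e-6 threshold
    spurious motifs essentially vanish.
    """
    from scipy.stats import binom as sp_binom

    n_seeds = 100
    _, proteome = planted_motif_windows(10, 50_000, motif=(1, "A"), enrichment=0.0, seed=999)
    background = BackgroundModel.from_proteome(proteome, half_width=5)
    bg_matrix = np.array([list(w) for w in background.windows])
    n_fg = 200

    # analytic oracle: expected number of false fixes at p<1e-3, min_occ 12
    lam = 0.0
    for j in range(11):
        if j == 5:
            continue
        col = bg_matrix[:, j]
        for aa in AMINO_ACIDS:
            p0 = (col == aa).mean()
            ks = np.arange(n_fg + 1)
            sf = sp_binom.sf(ks - 1, n_fg, p0)
            ok = (ks >= 12) & (sf < 1e-3)
            if ok.any():
                # attained level of "count >= k*": P(X >= k*) = sf at k*
                lam += float(sf[ks[ok][0]])
    p_any = 1.0 - math.exp(-lam)

    spurious_loose = spurious_strict = 0
    for seed in range(n_seeds):
        windows, _ = planted_motif_windows(n_fg, 10, motif=(1, "A"), enrichment=0.0, seed=seed)
        if motifx_extract(windows, background, p_threshold=1e-3):
            spurious_loose += 1
        if motifx_extract(windows, background, p_threshold=1e-6):
            spurious_strict += 1
    se = math.sqrt(n_seeds * p_any * (1 - p_any))
    assert abs(spurious_loose - n_seeds * p_any) < 3 * se + 2  # Poissonized bound
    assert n_seeds - spurious_strict >= 95  # stringent threshold: clean nulls


def test_motifx_motifs_are_mutually_exclusive():
    rng = np.random.default_rng(33)
    # two planted sub-populations with different fixed positions
    fg_a, proteome = planted_motif_windows(120, 30_000, motif=(-5, "K"), enrichment=1.0, seed=34)
    fg_b, _ = planted_motif_windows(120, 10, motif=(3, "P"), enrichment=1.0, seed=35)
    foreground = fg_a + fg_b
    background = BackgroundModel.from_proteome(proteome, half_width=5)
    motifs = motifx_extract(foreground, background)
    assert len(motifs) >= 2
    assert sum(m.n_matching for m in motifs) <= len(foreground)
    # every foreground window matches at most ... each motif's windows were
    # consumed, so matching counts of later motifs exclude earlier matches
    first = motifs[0]
    matches_first = [
        w for w in foreground
        if all(w[p + 5] == r for p, r in first.fixed)
    ]
    assert first.n_matching == len(matches_first)


def test_motifx_rejects_mismatched_widths():
    foreground, proteome = planted_motif_windows(20, 500, motif=(2, "A"), enrichment=1.0, seed=4)
    background = BackgroundModel.from_proteome(proteome, half_width=7)
    with pytest.raises(ValidationError, match="width"):
        motifx_extract(foreground, background)
    trimmed = trim_windows(background.windows, 5)
    assert all(len(w) == 11 for w in trimmed)


def test_motif_pattern_notation():
    def motif(fixed):
        steps = tuple(
            MotifStep(position=p, residue=r, p_value=1e-5, n_matching=20) for p, r in fixed
        )
        return Motif(steps=steps, n_matching=20, half_width=5)

    assert motif([(-5, "K")]).pattern == "KxxxxK(ac)"
    assert motif([(5, "K")]).pattern == "K(ac)xxxxK"
    assert motif([(-2, "A"), (1, "P")]).pattern == "AxK(ac)P"


def test_background_frequencies_sum_to_one():
    _, proteome = planted_motif_windows(1, 2000, motif=(1, "A"), enrichment=0.0, seed=6)
    model = BackgroundModel.from_proteome(proteome, half_width=5)
    freqs = model.frequencies()
    sums = freqs.sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, rtol=1e-9)
    assert freqs.loc["K", 0] == 1.0  # center column is all K


def test_heatmap_matches_exact_fisher_oracle():
    rng = np.random.default_rng(41)
    foreground, proteome = planted_motif_windows(
        30, 2000, motif=(-2, "A"), enrichment=0.7, seed=42, half_width=10
    )
    background = BackgroundModel.from_proteome(proteome, half_width=10)
    heat = residue_heatmap(foreground, background)
    assert heat.shape == (20, 21)
    assert heat[0].isna().all()  # center column masked
    fg_matrix = np.array([list(w) for w in foreground])
    bg_matrix = np.array([list(w) for w in background.windows])
    for j, offset in enumerate(heat.columns):
        if offset == 0:
            continue
        n_fg = int((fg_matrix[:, j] != "-").sum())
        n_bg = int((bg_matrix[:, j] != "-").sum())
        for aa in AMINO_ACIDS:
            k_fg = int((fg_matrix[:, j] == aa).sum())
            k_bg = int((bg_matrix[:, j] == aa).sum())
            p = exact_fisher_two_sided(k_fg, n_fg, k_bg, n_bg)
            cell = heat.loc[aa, offset]
            assert abs(cell) == pytest.approx(-math.log10(p), rel=1e-9, abs=1e-9)
            if k_fg / n_fg > k_bg / n_bg:
                assert cell > 0 or p == 1.0
            elif k_fg / n_fg < k_bg / n_bg:
                assert cell < 0 or p == 1.0


def test_heatmap_self_comparison_is_flat():
    windows, _ = planted_motif_windows(40, 10, motif=(1, "A"), enrichment=0.0, seed=44, half_width=10)
    heat = residue_heatmap(windows, windows)
    values = heat.drop(columns=[0]).to_numpy()
    assert np.nanmax(np.abs(values)) == 0.0  # identical proportions, p = 1


def test_heatmap_planted_enrichment_is_strongest_cell():
    foreground, proteome = planted_motif_windows(
        134, 50_000, motif=(-2, "A"), enrichment=0.6, seed=45, half_width=10
    )
    background = BackgroundModel.from_proteome(proteome, half_width=10)
    heat = residue_heatmap(foreground, background)
    assert heat.loc["A", -2] > 0
    assert heat.loc["A", -2] == np.nanmax(heat.to_numpy())


def test_heatmap_swapping_foreground_and_background_flips_signs():
    foreground, proteome = planted_motif_windows(
        50, 1500, motif=(3, "L"), enrichment=0.8, seed=46, half_width=10
    )
    background = BackgroundModel.from_proteome(proteome, half_width=10)
    bg_sample = list(background.windows)[:300]
    forward = residue_heatmap(foreground, bg_sample)
    backward = residue_heatmap(bg_sample, foreground)
    np.testing.assert_allclose(
        forward.drop(columns=[0]).to_numpy(),
        -backward.drop(columns=[0]).to_numpy(),
        rtol=1e-9,
        atol=1e-12,
    )


def test_heatmap_empty_foreground_is_error():
    windows, _ = planted_motif_windows(5, 10, motif=(1, "A"), enrichment=0.0, seed=47, half_width=10)
    with pytest.raises(ValidationError):
        residue_heatmap([], windows)
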