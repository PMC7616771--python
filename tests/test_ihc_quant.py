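"""Positivity calling: Otsu, pooled cutoffs, tile heatmaps, correlations."""

import numpy as np
import pytest

from marrowquant import ihc_quant as iq
from marrowquant import stain_deconv as sdv
from marrowquant import synthetic_data as sd


def otsu_bruteforce(counts, edges):
    """Independent oracle: exhaustive between-class-variance maximization
    over interior bin edges, lowest maximizing edge wins."""
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = None, -np.inf
    for k in range(1, counts.size):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, edges[k]
    return best_t


class TestOtsu:
    def test_two_cluster_values(self):
        values = [1, 1, 1, 7, 7, 7]
        edges = np.linspace(0, 8, 9)
        counts, _ = np.histogram(values, bins=edges)
        t = iq.otsu_threshold(histogram=(counts, edges))
        assert t == otsu_bruteforce(counts, edges)
        assert 1 < t <= 7

    def test_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            counts = rng.integers(0, 50, size=256)
            counts[rng.integers(0, 256)] += 100  # guarantee mass
            edges = np.linspace(0, 1, 257)
            assert iq.otsu_threshold(histogram=(counts, edges)) == \
                otsu_bruteforce(counts, edges)

    def test_gaussian_mixture_threshold_near_midpoint(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0.2, 0.05, 50_000),
                                 rng.normal(0.8, 0.05, 50_000)])
        t = iq.otsu_threshold(values)
        assert 0.4 < t < 0.6

    def test_constant_input_is_degenerate(self):
        with pytest.raises(iq.DegenerateInputError):
            iq.otsu_threshold(np.full(100, 3.0))

    def test_lowest_tie_rule(self):
        # symmetric histogram: two maximizing edges, the lower must win
        counts = np.array([5, 0, 0, 5])
        edges = np.linspace(0, 4, 5)
        t = iq.otsu_threshold(histogram=(counts, edges))
        assert t == otsu_bruteforce(counts, edges) == edges[1]


class TestTissueMask:
    def test_all_white_slide_has_empty_mask(self, hdab):
        slide = sdv.RgbSlide(np.full((16, 16, 3), 255, dtype=np.uint8), 1.0)
        assert not iq.tissue_mask(slide, hdab).any()

    def test_matches_generator_truth(self, hdab):
        spec = sd.IhcSimSpec(width_px=100, height_px=100, tissue_fraction=0.6,
                             noise_sd=0.0, seed=21)
        slide, truth = sd.gen_ihc_slide(spec, hdab)
        assert np.array_equal(iq.tissue_mask(slide, hdab), truth.tissue_mask)

    def test_threshold_monotonicity(self, hdab):
        spec = sd.IhcSimSpec(width_px=64, height_px=64, noise_sd=0.1, seed=22)
        slide, _ = sd.gen_ihc_slide(spec, hdab)
        loose = iq.tissue_mask(slide, hdab, od_min=0.0)
        strict = iq.tissue_mask(slide, hdab, od_min=0.15)
        assert np.all(loose[strict])  # strict subset of loose


class TestPooledCutoff:
    def _cohort(self, hdab, n, seed0=30):
        slides = []
        for i in range(n):
            spec = sd.IhcSimSpec(width_px=96, height_px=96, seed=seed0 + i,
                                 noise_sd=0.02)
            slides.append(sd.gen_ihc_slide(spec, hdab)[0])
        return slides

    def test_single_slide_equals_per_slide_otsu(self, hdab):
        slide = self._cohort(hdab, 1)[0]
        mask = iq.tissue_mask(slide, hdab)
        conc = sdv.deconvolve_slide(slide, hdab)
        cut = iq.pooled_positive_cutoff([slide], hdab)
        assert cut.cutoff == iq.otsu_threshold(conc.chromogen[mask])

    def test_order_invariance(self, hdab):
        slides = self._cohort(hdab, 3)
        c1 = iq.pooled_positive_cutoff(slides, hdab)
        c2 = iq.pooled_positive_cutoff(slides[::-1], hdab)
        assert c1.cutoff == c2.cutoff
        assert c1.n_pixels_pooled == c2.n_pixels_pooled

    def test_bimodal_cohort_classified_per_design(self, hdab):
        slides, truths = [], []
        for i in range(4):
            spec = sd.IhcSimSpec(width_px=96, height_px=96, seed=40 + i,
                                 chromogen_conc_pos=1.0,
                                 chromogen_conc_neg=0.1, noise_sd=0.02)
            s, t = sd.gen_ihc_slide(spec, hdab)
            slides.append(s)
            truths.append(t)
        cut = iq.pooled_positive_cutoff(slides, hdab)
        assert 0.1 < cut.cutoff < 1.0
        correct = total = 0
        for s, t in zip(slides, truths):
            conc = sdv.deconvolve_slide(s, hdab)
            called = conc.chromogen > cut.cutoff
            correct += (called == t.positive_mask)[t.tissue_mask].sum()
            total += t.tissue_mask.sum()
        assert correct / total >= 0.99


class TestHeatmap:
    def _slide_pipeline(self, hdab, seed, **kw):
        spec = sd.IhcSimSpec(width_px=200, height_px=200, seed=seed,
                             noise_sd=0.02, **kw)
        slide, truth = sd.gen_ihc_slide(spec, hdab)
        mask = iq.tissue_mask(slide, hdab)
        conc = sdv.deconvolve_slide(slide, hdab)
        cut = iq.pooled_positive_cutoff([slide], hdab)
        return conc, mask, cut

    def test_saturated_slide_has_ratio_one(self, hdab):
        conc = sdv.ConcentrationMaps(np.full((64, 64, 3), 1.0))
        mask = np.ones((64, 64), bool)
        hm = iq.positivity_heatmap(conc, mask, 0.5, 16, 1.0)
        assert np.all(hm.ratio == 1.0)

    def test_checkerboard_gives_half(self):
        maps = np.zeros((64, 64, 3))
        rr, cc = np.mgrid[0:64, 0:64]
        maps[..., 0] = ((rr + cc) % 2).astype(float)
        hm = iq.positivity_heatmap(sdv.ConcentrationMaps(maps),
                                   np.ones((64, 64), bool), 0.5, 16, 1.0)
        assert np.all(hm.ratio == 0.5)

    def test_conservation_identity(self, hdab):
        conc, mask, cut = self._slide_pipeline(hdab, 50)
        hm = iq.positivity_heatmap(conc, mask, cut, 64, 1.5)  # partial tiles
        assert hm.slide_tissue == mask.sum()
        assert abs(hm.tissue_weighted_mean_ratio - hm.slide_ratio) < 1e-12

    def test_raising_cutoff_never_raises_ratios(self, hdab):
        conc, mask, cut = self._slide_pipeline(hdab, 51)
        lo = iq.positivity_heatmap(conc, mask, cut.cutoff, 50, 1.0)
        hi = iq.positivity_heatmap(conc, mask, cut.cutoff + 0.1, 50, 1.0)
        ok = ~np.isnan(lo.ratio)
        assert np.all(hi.ratio[ok] <= lo.ratio[ok])

    def test_zero_tissue_tiles_missing(self, hdab):
        conc, mask, cut = self._slide_pipeline(hdab, 52, tissue_fraction=0.25)
        hm = iq.positivity_heatmap(conc, mask, cut, 40, 1.0)
        assert np.isnan(hm.ratio[hm.tissue_px == 0]).all()

    def test_shape_mismatch_rejected(self):
        conc = sdv.ConcentrationMaps(np.zeros((8, 8, 3)))
        with pytest.raises(ValueError):
            iq.positivity_heatmap(conc, np.ones((4, 4), bool), 0.5, 4, 1.0)


class TestPerField:
    def test_whole_image_field_equals_slide_ratio(self, hdab):
        spec = sd.IhcSimSpec(width_px=80, height_px=80, seed=60, noise_sd=0.02)
        slide, _ = sd.gen_ihc_slide(spec, hdab)
        mask = iq.tissue_mask(slide, hdab)
        conc = sdv.deconvolve_slide(slide, hdab)
        cut = iq.pooled_positive_cutoff([slide], hdab)
        fields = iq.per_field_positivity(conc, mask, cut, field_size_um=80,
                                         microns_per_pixel=1.0)
        hm = iq.positivity_heatmap(conc, mask, cut, 80, 1.0)
        assert len(fields) == 1
        assert fields[0].positive_ratio == hm.slide_ratio

    def test_group_separation_detected(self, hdab):
        """Low-positivity vs high-positivity cohorts separate by rank-sum."""
        from marrowquant import group_stats as st
        per_group = {}
        for group, frac, seed0 in [("HD", 0.05, 70), ("MF", 0.40, 80)]:
            vals = []
            for i in range(2):
                spec = sd.IhcSimSpec(width_px=192, height_px=192,
                                     positive_fraction=frac, seed=seed0 + i,
                                     noise_sd=0.02)
                slide, truth = sd.gen_ihc_slide(spec, hdab)
                conc = sdv.deconvolve_slide(slide, hdab)
                cut = 0.4  # between designed neg (0.1) and pos (0.8)
                fields = iq.per_field_positivity(
                    conc, truth.tissue_mask, cut, field_size_um=48,
                    microns_per_pixel=1.0, group=group)
                vals += [f.positive_ratio for f in fields]
            per_group[group] = vals
        res = st.wilcoxon_rank_sum(per_group["HD"], per_group["MF"])
        assert res.p < 0.001


class TestDensityCorrelation:
    def _heatmap(self, hdab, tiles=20):
        spec = sd.IhcSimSpec(width_px=400, height_px=400, seed=90,
                             noise_sd=0.05)
        slide, truth = sd.gen_ihc_slide(spec, hdab)
        conc = sdv.deconvolve_slide(slide, hdab)
        return iq.positivity_heatmap(conc, truth.tissue_mask, 0.4,
                                     400 // tiles, 1.0)

    def test_identity_and_reversal(self, hdab):
        hm = self._heatmap(hdab)
        rho, _, n = iq.intensity_density_correlation(hm, hm.ratio.copy())
        assert rho == 1.0 and n == hm.ratio.size
        rho_rev, _, _ = iq.intensity_density_correlation(hm, -hm.ratio)
        assert rho_rev == -1.0

    def test_permutation_null_is_uncorrelated(self, hdab):
        hm = self._heatmap(hdab)
        rng = np.random.default_rng(123)
        permuted = rng.permutation(hm.ratio.ravel()).reshape(hm.ratio.shape)
        rho, _, n = iq.intensity_density_correlation(hm, permuted)
        assert n == 400
        assert abs(rho) < 0.15

    def test_insufficient_pairs_rejected(self, hdab):
        hm = self._heatmap(hdab)
        density = np.full(hm.ratio.shape, np.nan)
        density[0, 0] = density[0, 1] = 0.5
        with pytest.raises(iq.InsufficientDataError):
            iq.intensity_density_correlation(hm, density)
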