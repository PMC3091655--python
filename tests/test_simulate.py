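import numpy as np
import pytest

from hetchrom.features import classify_tandem_repeat, filter_segmental_duplication
from hetchrom.regions import ChromatinRegion, load_agamp3_regions
from hetchrom.simulate import (
    SimulationSpec,
    gen_analysis_windows,
    gen_chromatin_map,
    gen_feature_intervals,
    gen_go_annotations,
    gen_window_counts,
)


class TestChromatinMap:
    def test_matches_template_structure(self):
        spec = SimulationSpec(seed=1)
        regions = gen_chromatin_map(spec)
        template = load_agamp3_regions()
        assert [(r.arm, r.chromatin_class) for r in regions] == [
            (r.arm, r.chromatin_class) for r in template
        ]
        assert [r.size for r in regions] == [r.size for r in template]

    def test_scaling_is_linear(self):
        spec = SimulationSpec(seed=1, scale=0.01)
        regions = gen_chromatin_map(spec)
        template = load_agamp3_regions()
        for r, t in zip(regions, template):
            assert r.size == pytest.approx(t.size * 0.01, abs=1)

    def test_generated_map_passes_region_validation(self, tmp_path):
        from hetchrom.regions import read_region_table

        spec = SimulationSpec(seed=9, scale=0.05)
        regions = gen_chromatin_map(spec)
        rows = ["arm\tclass\tstart\tend"]
        rows += [
            f"{r.arm}\t{r.chromatin_class}\t{r.start}\t{r.end}" for r in regions
        ]
        p = tmp_path / "map.tsv"
        p.write_text("".join(line + "\n" for line in rows))
        back = read_region_table(p)
        assert len(back) == len(regions)

    def test_unknown_template_rejected(self):
        spec = SimulationSpec(seed=1)
        spec.template = "something-else"
        with pytest.raises(ValueError):
            gen_chromatin_map(spec)


class TestFeatureIntervals:
    def test_zero_density_gives_no_intervals(self):
        spec = SimulationSpec(seed=2)
        for f in spec.density:
            spec.density[f] = {c: 0.0 for c in spec.density[f]}
        regions = gen_chromatin_map(spec)
        assert gen_feature_intervals(regions, spec) == []

    def test_coverage_fraction_calibrated(self):
        # one 10-Mb region, target coverage 25%: over replicates the mean
        # realized union fraction must sit within 3 MC standard errors
        region = ChromatinRegion("X", "EU", 1, 10_000_001)
        target = 0.25
        fractions = []
        for rep in range(300):
            spec = SimulationSpec(seed=10_000 + rep)
            spec.density["gene"]["EU"] = 20.0
            spec.coverage["gene"]["EU"] = target
            ivs = gen_feature_intervals([region], spec, ["gene"])
            spans = sorted((iv.start, iv.end) for iv in ivs)
            covered, last_end = 0, 0
            for s, e in spans:
                s = max(s, last_end)
                if e > s:
                    covered += e - s
                    last_end = e
            fractions.append(covered / region.size)
        mean = np.mean(fractions)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean - target) < 3 * se + 1e-4

    def test_infeasible_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage fraction"):
            SimulationSpec(seed=1, coverage={"gene": {"EU": 1.2}})

    def test_generated_repeats_pass_their_own_filters(self):
        spec = SimulationSpec(seed=4, scale=0.1)
        regions = gen_chromatin_map(spec)
        ivs = gen_feature_intervals(regions, spec)
        tandem = [iv for iv in ivs if iv.period is not None]
        assert tandem, "expected some tandem repeats"
        for iv in tandem:
            assert (
                classify_tandem_repeat(iv.period, iv.copy_number, iv.percent_match)
                == iv.feature_class
            )
        sds = [iv for iv in ivs if iv.feature_class == "sd"]
        assert sds, "expected some segmental duplications"
        for iv in sds:
            assert filter_segmental_duplication(iv.aligned_length, iv.percent_identity)

    def test_deterministic_under_seed(self):
        a = gen_feature_intervals(
            gen_chromatin_map(SimulationSpec(seed=6, scale=0.05)),
            SimulationSpec(seed=6, scale=0.05),
        )
        b = gen_feature_intervals(
            gen_chromatin_map(SimulationSpec(seed=6, scale=0.05)),
            SimulationSpec(seed=6, scale=0.05),
        )
        assert a == b


class TestAnalysisWindows:
    def test_tiling_and_bounds(self):
        spec = SimulationSpec(seed=8)
        regions = gen_chromatin_map(spec)
        ws = gen_analysis_windows(regions, spec, 250_000, 50_000)
        by_pos = {}
        for w in ws:
            by_pos.setdefault(w.arm, []).append(w)
            limit = 250_000 if w.chromatin_class in ("EU", "PEU") else 50_000
            assert 0 < w.length <= limit
        assert sum(w.length for w in ws) == sum(r.size for r in regions)

    def test_lengths_vary_within_class(self):
        spec = SimulationSpec(seed=8)
        ws = gen_analysis_windows(gen_chromatin_map(spec), spec, 250_000, 50_000)
        eu_lengths = [w.length for w in ws if w.chromatin_class == "EU"]
        assert np.std(np.log(eu_lengths)) > 0.1


class TestWindowCounts:
    def test_deterministic_under_seed(self):
        spec = SimulationSpec(seed=12)
        regions = gen_chromatin_map(spec)
        ws = gen_analysis_windows(regions, spec, 500_000, 100_000)
        a = gen_window_counts(ws, SimulationSpec(seed=12))
        b = gen_window_counts(ws, SimulationSpec(seed=12))
        assert a == b

    def test_very_negative_intercept_silences_counts(self):
        spec = SimulationSpec(seed=13)
        for c in spec.planted_params.mu:
            spec.planted_params.mu[c] = -40.0
        regions = gen_chromatin_map(spec)
        ws = gen_analysis_windows(regions, spec, 500_000, 100_000)
        recs = gen_window_counts(ws, spec)
        assert all(r.count == 0 for r in recs)

    def test_empirical_means_match_rates(self):
        # at n = 5,000 identical windows the empirical mean count per class
        # sits within 3 standard errors of the planted Poisson rate
        from hetchrom.features import GenomicWindow

        spec = SimulationSpec(seed=14)
        L, f = 100_000, spec.coverage["rna_te"]
        windows = [
            GenomicWindow("X", 1 + i * L, 1 + (i + 1) * L, cls)
            for cls in ("EU", "PH")
            for i in range(5000)
        ]
        recs = gen_window_counts(windows, spec)
        params = spec.planted_params
        for cls in ("EU", "PH"):
            sub = [r for r in recs if r.window.chromatin_class == cls]
            counts = np.array([r.count for r in sub], float)
            lam = np.array(
                [
                    np.exp(
                        params.mu[cls]
                        + params.beta[cls] * np.log(r.window.length)
                        + params.zeta[cls] * np.log(r.coverage + 1)
                    )
                    for r in sub
                ]
            )
            se = np.sqrt((lam + lam**2).mean() / len(sub))  # conservative
            assert abs(counts.mean() - lam.mean()) < 3 * se


class TestGoAnnotations:
    def test_factor_one_matches_background(self):
        spec = SimulationSpec(seed=15, go_enrichment_factor=1.0, go_n_study=500)
        ann, study, planted = gen_go_annotations(spec)
        term = planted[0]
        q = sum(term in ts for ts in ann.values()) / len(ann)
        p = sum(term in ann[g] for g in study) / len(study)
        assert abs(p - q) < 3 * np.sqrt(q * (1 - q) / len(study)) + 0.01

    def test_factor_ten_plants_tenfold_frequency(self):
        reps = [
            gen_go_annotations(SimulationSpec(seed=100 + i, go_n_study=200))
            for i in range(20)
        ]
        ratios = []
        for ann, study, planted in reps:
            term = planted[0]
            q = sum(term in ts for ts in ann.values()) / len(ann)
            p = sum(term in ann[g] for g in study) / len(study)
            if q > 0:
                ratios.append(p / q)
        assert np.mean(ratios) == pytest.approx(10.0, rel=0.2)

    def test_depletion_factor_rejected(self):
        spec = SimulationSpec(seed=1, go_enrichment_factor=0.5)
        with pytest.raises(ValueError, match="factor"):
            gen_go_annotations(spec)

    def test_deterministic_under_seed(self):
        a = gen_go_annotations(SimulationSpec(seed=44))
        b = gen_go_annotations(SimulationSpec(seed=44))
        assert a == b

    def test_study_is_subset_of_background(self):
        ann, study, _ = gen_go_annotations(SimulationSpec(seed=45))
        assert set(study) <= set(ann)
        assert len(study) == 100
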