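import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpopgen import filtering as fl
from txpopgen.model import MISSING, ConfigurationError, FilterThresholds

from conftest import make_record
from oracles import naive_filter

SIX_MASKS = {
    "A": np.array([True, True, True, False, False, False]),
    "B": np.array([False, False, False, True, True, True]),
}


class TestGenotypeMasking:
    @pytest.mark.parametrize("gq,masked", [(19, True), (20, False)])
    def test_boundary(self, gq, masked):
        rec = make_record(genotypes=[1] * 6, gq=[gq] * 6)
        out, n = fl.mask_low_quality_genotypes([rec], gq_min=20)
        assert (out[0].genotypes == MISSING).all() == masked
        assert n == (6 if masked else 0)

    def test_count_from_mixed_gqs(self):
        rec = make_record(
            genotypes=[0, 1, 2, 0, 1],
            gq=[10, 19, 20, 21, 99],
            samples=tuple(f"s{i}" for i in range(5)),
        )
        out, n = fl.mask_low_quality_genotypes([rec], gq_min=20)
        assert n == 2
        assert list(out[0].genotypes) == [MISSING, MISSING, 2, 0, 1]

    def test_site_fields_untouched(self):
        rec = make_record(gq=[5] * 6, fs=3.25, qd=11.0, depth=77)
        out, _ = fl.mask_low_quality_genotypes([rec], gq_min=20)
        assert out[0].fs == 3.25 and out[0].qd == 11.0 and out[0].depth == 77


class TestSnpClusters:
    def brute(self, positions, window=35, max_snps=3):
        removed = set()
        for w in range(1, max(positions) + 1):
            inside = [p for p in positions if w <= p <= w + window - 1]
            if len(inside) > max_snps:
                removed.update(inside)
        return removed

    @pytest.mark.parametrize(
        "positions,expected_removed",
        [
            ((1, 10, 20, 34), {1, 10, 20, 34}),  # span 34 <= 35, count 4 > 3
            ((1, 10, 20), set()),  # 3 is not "more than 3"
            ((1, 40, 80, 120), set()),  # no window holds > 3
        ],
    )
    def test_spec_examples(self, positions, expected_removed):
        records = [make_record(pos=p) for p in positions]
        removed = fl.flag_snp_clusters(records, 35, 3)
        assert {p for _, p in removed} == expected_removed
        assert removed == {("g1", p) for p in self.brute(positions)}

    @given(
        positions=st.lists(
            st.integers(min_value=1, max_value=200), min_size=1, max_size=15,
            unique=True,
        ),
        window=st.integers(min_value=2, max_value=50),
        max_snps=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_scan(self, positions, window, max_snps):
        records = [make_record(pos=p) for p in positions]
        got = {p for _, p in fl.flag_snp_clusters(records, window, max_snps)}
        assert got == self.brute(positions, window, max_snps)

    def test_clusters_are_per_unigene(self):
        records = [make_record(unigene=u, pos=p)
                   for u in ("g1", "g2") for p in (1, 10)]
        assert fl.flag_snp_clusters(records, 35, 3) == set()


def lenient(**kw):
    base = dict(
        fs_max=30, qd_min=2, depth_min=25, gq_min=20,
        min_called_per_pop=1, maf_min=0.0,
    )
    base.update(kw)
    return FilterThresholds(**base)


class TestSiteFilters:
    def test_fs_boundary_is_strict(self):
        rec = make_record(fs=30.0)
        out = fl.apply_site_filters([rec], lenient(), SIX_MASKS)
        assert len(out.kept) == 1
        rec2 = make_record(fs=30.25)
        out2 = fl.apply_site_filters([rec2], lenient(), SIX_MASKS)
        assert out2.removed_by_rule["fs"] == 1

    def test_maf_rule(self):
        # 96 individuals all called, 1 alt copy of 192 -> MAF 0.0052 < 0.01
        samples = tuple(f"s{i}" for i in range(96))
        masks = {
            "A": np.arange(96) < 48,
            "B": np.arange(96) >= 48,
        }
        gts = [1] + [0] * 95
        rec = make_record(genotypes=gts, samples=samples)
        out = fl.apply_site_filters(
            [rec], lenient(min_called_per_pop=16, maf_min=0.01), masks
        )
        assert out.removed_by_rule["maf"] == 1
        assert 1 / 192 == pytest.approx(0.00521, abs=1e-5)

    def test_presence_rule(self):
        samples = tuple(f"s{i}" for i in range(96))
        masks = {"A": np.arange(96) < 48, "B": np.arange(96) >= 48}
        gts = np.ones(96, dtype=np.int8)
        gts[:33] = MISSING  # 15 called in A, 48 in B
        rec = make_record(genotypes=gts, samples=samples)
        out = fl.apply_site_filters(
            [rec], lenient(min_called_per_pop=16), masks
        )
        assert out.removed_by_rule["min_called_per_pop"] == 1

    def test_missing_info_strict_vs_lax(self):
        rec = make_record(fs=None)
        strict = fl.apply_site_filters([rec], lenient(), SIX_MASKS)
        assert strict.removed_by_rule["fs"] == 1
        lax = fl.apply_site_filters(
            [rec], dataclasses.replace(lenient(), strict_info=False), SIX_MASKS
        )
        assert len(lax.kept) == 1

    def test_invalid_thresholds(self):
        with pytest.raises(ConfigurationError):
            FilterThresholds(fs_max=-1)
        with pytest.raises(ConfigurationError):
            FilterThresholds(cluster_window=0)


def random_records(rng, n=30, n_samples=6):
    samples = tuple(f"s{i}" for i in range(n_samples))
    recs = []
    used = set()
    for _ in range(n):
        gene = f"g{rng.integers(1, 4)}"
        pos = int(rng.integers(1, 120))
        if (gene, pos) in used:
            continue
        used.add((gene, pos))
        recs.append(
            make_record(
                unigene=gene,
                pos=pos,
                genotypes=rng.integers(-1, 3, size=n_samples),
                gq=rng.integers(0, 100, size=n_samples),
                samples=samples,
                fs=float(rng.uniform(0, 40)) if rng.random() > 0.1 else None,
                qd=float(rng.uniform(0, 35)) if rng.random() > 0.1 else None,
                depth=int(rng.integers(0, 100)) if rng.random() > 0.1 else None,
            )
        )
    return recs


class TestCascadeProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng)
        t = FilterThresholds(depth_min=25, min_called_per_pop=2, maf_min=0.05)
        masked, _ = fl.mask_low_quality_genotypes(records, t.gq_min)
        out = fl.apply_site_filters(masked, t, SIX_MASKS)
        oracle_kept, oracle_removed = naive_filter(masked, t, SIX_MASKS)
        assert [(r.unigene_id, r.pos) for r in out.kept] == oracle_kept
        assert {k: v for k, v in out.removed_by_rule.items() if v} == oracle_removed

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_and_idempotence(self, seed):
        rng = np.random.default_rng(100 + seed)
        records = random_records(rng)
        t = FilterThresholds(min_called_per_pop=2, maf_min=0.05)
        out = fl.run_filters(records, t, SIX_MASKS)
        assert len(out.kept) + out.n_removed == len(records)
        again = fl.run_filters(out.kept, t, SIX_MASKS)
        assert len(again.kept) == len(out.kept)
        assert again.n_removed == 0

    @given(
        seed=st.integers(0, 10_000),
        fs_max=st.floats(5, 40),
        qd_min=st.floats(0, 10),
        depth_min=st.integers(0, 60),
        gq_min=st.integers(0, 60),
        maf_min=st.floats(0, 0.3),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotonicity(self, seed, fs_max, qd_min, depth_min, gq_min, maf_min):
        """Tightening any site-level threshold never increases the kept
        count. (gq_min is excluded: masking more genotypes changes the
        pooled MAF, which can legitimately rescue a site from the MAF
        rule, so the cascade is not monotone in gq_min.)"""
        rng = np.random.default_rng(seed)
        records = random_records(rng, n=20)
        base = FilterThresholds(
            fs_max=fs_max, qd_min=qd_min, depth_min=depth_min,
            gq_min=gq_min, min_called_per_pop=1, maf_min=maf_min,
        )
        n_base = len(fl.run_filters(records, base, SIX_MASKS).kept)
        tighter = [
            dataclasses.replace(base, fs_max=fs_max - 2),
            dataclasses.replace(base, qd_min=qd_min + 2),
            dataclasses.replace(base, depth_min=depth_min + 10),
            dataclasses.replace(base, min_called_per_pop=2),
            dataclasses.replace(base, maf_min=min(maf_min + 0.1, 0.5)),
        ]
        for t in tighter:
            assert len(fl.run_filters(records, t, SIX_MASKS).kept) <= n_base

    def test_gq_monotone_in_masked_genotypes(self):
        """What IS monotone in gq_min: the number of masked genotypes."""
        rng = np.random.default_rng(42)
        records = random_records(rng, n=20)
        masked_counts = [
            fl.mask_low_quality_genotypes(records, gq)[1] for gq in (0, 20, 40, 99)
        ]
        assert masked_counts == sorted(masked_counts)


class TestPlantedArtifacts:
    def test_planted_sites_removed_by_their_rule(self, planted_sim):
        sim = planted_sim
        masks = sim.sheet.masks(sim.sheet.samples)
        t = FilterThresholds()
        out = fl.run_filters(sim.records, t, masks)
        kept_keys = {(r.unigene_id, r.pos) for r in out.kept}
        truth = sim.truth
        for g, p in truth["fs_fail"]:
            assert (g, p) not in kept_keys
        for g, p in truth["qd_fail"]:
            assert (g, p) not in kept_keys
        for g, p in truth["depth_fail"]:
            assert (g, p) not in kept_keys
        # baseline FS/QD/depth cannot violate, so per-rule counts are exact
        assert out.removed_by_rule["fs"] == len(truth["fs_fail"])
        assert out.removed_by_rule["qd"] == len(truth["qd_fail"])
        assert out.removed_by_rule["depth"] == len(truth["depth_fail"])
        # every planted cluster gene loses all four of its SNPs
        for gene in truth["cluster_genes"]:
            assert all(k[0] != gene for k in kept_keys)

    def test_survivors_match_naive_oracle(self, planted_sim):
        sim = planted_sim
        masks = sim.sheet.masks(sim.sheet.samples)
        t = FilterThresholds()
        masked, _ = fl.mask_low_quality_genotypes(sim.records, t.gq_min)
        out = fl.apply_site_filters(masked, t, masks)
        oracle_kept, oracle_removed = naive_filter(masked, t, masks)
        assert [(r.unigene_id, r.pos) for r in out.kept] == oracle_kept
        assert {k: v for k, v in out.removed_by_rule.items() if v} == oracle_removed
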