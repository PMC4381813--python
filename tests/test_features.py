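"""Coverage tracks, duplication calls, contact profiles, correlation shift."""

import numpy as np
import pandas as pd
import pytest

from meta3c import (HPAII, BinningScheme, LibraryConfig, Replicon, digest,
                    digest_genome, make_bins, simulate)
from meta3c.contact_map import ContactMatrix, build_matrix, scn_normalize
from meta3c.features import (contact_profile, correlation_shift,
                             coverage_track, detect_duplications)
from meta3c.simulate import (fprime_community, simulate_genomes,
                             simulate_pairs)


def toy_bins(n_bins=10, bin_len=1000):
    seq = ("A" * (bin_len - 4) + "CCGG") * n_bins
    fm = digest(Replicon("r", seq, False), HPAII)
    return make_bins(fm, BinningScheme("fragments", 1))


def uniform_pairs(rng, n, L, ref="r"):
    pos = rng.integers(0, L, size=(n, 2))
    return pd.DataFrame({"readid": np.arange(n).astype(str),
                         "ref1": ref, "pos1": pos[:, 0], "strand1": "+",
                         "ref2": ref, "pos2": pos[:, 1], "strand2": "-"})


class TestCoverage:
    def test_uniform_coverage_near_one(self, rng):
        bt = toy_bins(10)
        cov = coverage_track(uniform_pairs(rng, 50_000, 10_000), bt)
        # 1e5 ends over the ten ~1 kb bins: multinomial fluctuation only
        # (the digest leaves a 3 bp terminal fragment bin, skip it)
        wide = cov[(cov["end"] - cov["start"]) > 900]
        assert np.all(np.abs(wide["norm"] - 1.0) < 0.05)

    def test_median_normalization_exact(self, rng):
        bt = toy_bins(9)
        cov = coverage_track(uniform_pairs(rng, 5000, 9000), bt)
        nonempty = cov[cov["count"] > 0]
        assert np.median(nonempty["norm"]) == pytest.approx(1.0)

    def test_empty_bin_excluded_from_median(self, rng):
        bt = toy_bins(10)
        pairs = uniform_pairs(rng, 2000, 5000)   # only first 5 bins covered
        cov = coverage_track(pairs, bt)
        assert (cov["norm"].iloc[6:] == 0).all()
        assert np.median(cov.loc[cov["count"] > 0, "norm"]) == \
            pytest.approx(1.0)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            coverage_track(pd.DataFrame(columns=["ref1", "pos1", "ref2",
                                                 "pos2"]), toy_bins(3))


class TestDetectDuplications:
    def _track(self, norms):
        n = len(norms)
        return pd.DataFrame({"bin": range(n), "replicon": "r",
                             "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000,
                             "count": 100, "norm": norms})

    def test_flat_track_no_calls(self):
        calls = detect_duplications(self._track([1.0] * 20))
        assert len(calls) == 0

    def test_fourteen_bin_run_called(self):
        norms = [1.0] * 5 + [2.0] * 14 + [1.0] * 5
        calls = detect_duplications(self._track(norms), 1.6, 3)
        assert len(calls) == 1
        call = calls.iloc[0]
        assert (call["first_bin"], call["last_bin"]) == (5, 18)
        assert call["mean_ratio"] == pytest.approx(2.0)

    def test_single_spike_not_called(self):
        norms = [1.0] * 10 + [5.0] + [1.0] * 10
        calls = detect_duplications(self._track(norms), 1.6, 3)
        assert len(calls) == 0

    def test_runs_do_not_cross_replicons(self):
        a = self._track([2.0] * 2)
        b = self._track([2.0] * 2)
        b["replicon"] = "q"
        calls = detect_duplications(pd.concat([a, b], ignore_index=True),
                                    1.6, 3)
        assert len(calls) == 0   # 2+2 bins on different replicons: no run >= 3


class TestContactProfile:
    def _scn(self, m):
        n = m.shape[0]
        bins = pd.DataFrame({"bin": range(n), "replicon": "r",
                             "start": np.arange(n), "end": np.arange(n) + 1})
        return ContactMatrix(m, bins, state="scn")

    def test_single_bin_query_is_its_row(self):
        m = np.array([[0, .6, .4], [.6, 0, .4], [.4, .4, .2]])
        prof = contact_profile(self._scn(m), [0])
        assert prof["value"].to_list() == [0.6, 0.4]

    def test_uniform_matrix_constant_profile(self):
        m = np.full((5, 5), 0.25)
        prof = contact_profile(self._scn(m), [0, 1])
        assert np.allclose(prof["value"], 0.25)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            contact_profile(self._scn(np.eye(3)), [])

    def test_plasmid_prefers_host(self):
        """A plasmid sharing a cell with species A contacts A's chromosome
        far more than species B's."""
        cfg = simulate.CommunityConfig(
            species=(
                simulate.SpeciesSpec("a", (
                    simulate.RepliconSpec("a_chr", 150_000, True),
                    simulate.RepliconSpec("a_plasmid", 30_000, True))),
                simulate.SpeciesSpec("b", (
                    simulate.RepliconSpec("b_chr", 150_000, True),)),
            ), seed=61)
        com = simulate_genomes(cfg)
        pairs = simulate_pairs(com, LibraryConfig(n_pairs=400_000,
                                                  p_trans_replicon=0.2),
                               seed=62)
        fm = digest_genome(com.replicons.values(), HPAII)
        bt = make_bins(fm, BinningScheme("basepairs", 5000))
        scn = scn_normalize(build_matrix(pairs, bt))
        plasmid_bins = np.flatnonzero(
            (scn.bins["replicon"] == "a_plasmid").to_numpy())
        prof = contact_profile(scn, plasmid_bins)
        mean_a = prof.loc[prof["replicon"] == "a_chr", "value"].mean()
        mean_b = prof.loc[prof["replicon"] == "b_chr", "value"].mean()
        assert mean_a > 10 * mean_b


class TestCorrelationShift:
    def _constructed(self, n=40, lo=10, hi=20, seed=0):
        """Matrix whose rows inside [lo, hi) mirror the query profile.

        Only the special rows (region + query) carry a shared contact
        signature, and only over ordinary columns — the special x special
        block stays at background noise so background rows gain no
        systematic elevation through symmetry.
        """
        rng = np.random.default_rng(seed)
        n_query = 4
        total = n + n_query
        m = rng.random((total, total)) * 0.05
        m = (m + m.T) / 2
        special = list(range(lo, hi)) + list(range(n, total))
        ordinary = [c for c in range(total) if c not in special]
        signature = rng.normal(0.0, 0.5, len(ordinary))
        for s in special:
            vals = signature + rng.normal(0, 0.01, len(ordinary))
            m[s, ordinary] = vals
            m[ordinary, s] = vals
        np.fill_diagonal(m, 0)
        bins = pd.DataFrame({"bin": range(total), "replicon": "r",
                             "start": np.arange(total),
                             "end": np.arange(total) + 1})
        return ContactMatrix(m, bins, state="scn"), list(
            range(n, total)), lo, hi

    def test_constructed_region_localized(self):
        cm, query, lo, hi = self._constructed()
        shift = correlation_shift(cm, query, window=5)
        assert shift.change_start is not None
        assert abs(shift.change_start - lo) <= 1
        assert abs(shift.change_end - (hi - 1)) <= 1
        inside = shift.curve["r"][(shift.curve["bin"] >= lo)
                                  & (shift.curve["bin"] < hi)]
        outside = shift.curve["r"][(shift.curve["bin"] < lo)]
        assert inside.mean() > 0.8
        assert outside.mean() < 0.3

    def test_no_structure_no_changepoint(self, rng):
        n = 30
        m = rng.random((n, n)) * 0.1
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        bins = pd.DataFrame({"bin": range(n), "replicon": "r",
                             "start": np.arange(n), "end": np.arange(n) + 1})
        cm = ContactMatrix(m, bins, state="scn")
        shift = correlation_shift(cm, [0, 1], window=5)
        assert shift.change_start is None

    def test_window_validation(self):
        cm, query, *_ = self._constructed()
        with pytest.raises(ValueError):
            correlation_shift(cm, query, window=2)


@pytest.fixture(scope="module")
def fprime_run():
    cfg = fprime_community(seed=71)
    com = simulate_genomes(cfg)
    pairs = simulate_pairs(com, LibraryConfig(n_pairs=600_000,
                                              p_trans_replicon=0.1),
                           seed=72)
    fm = digest_genome(com.replicons.values(), HPAII)
    bt = make_bins(fm, BinningScheme("basepairs", 10_000))
    return com, pairs, bt, cfg.duplication


class TestFPrimeEndToEnd:
    def test_planted_duplication_doubles_coverage(self, fprime_run):
        com, pairs, bt, dup = fprime_run
        cov = coverage_track(pairs, bt)
        in_dup = ((cov["replicon"] == dup.source)
                  & (cov["start"] >= dup.start) & (cov["end"] <= dup.end))
        assert cov.loc[in_dup, "norm"].mean() == pytest.approx(2.0, abs=0.2)

    def test_duplication_called_with_tight_boundaries(self, fprime_run):
        com, pairs, bt, dup = fprime_run
        cov = coverage_track(pairs, bt)
        calls = detect_duplications(cov, 1.6, 3)
        calls = calls[calls["replicon"] == dup.source]
        assert len(calls) == 1
        call = calls.iloc[0]
        bin_width = 10_000
        assert abs(call["start"] - dup.start) <= 2 * bin_width
        assert abs(call["end"] - dup.end) <= 2 * bin_width

    def test_correlation_shift_finds_breakpoints(self, fprime_run):
        com, pairs, bt, dup = fprime_run
        scn = scn_normalize(build_matrix(pairs, bt))
        plasmid_bins = np.flatnonzero(
            (scn.bins["replicon"] == dup.target).to_numpy())
        shift = correlation_shift(scn, plasmid_bins, window=5)
        assert shift.change_start is not None
        start_bp = scn.bins.loc[shift.change_start, "start"]
        end_bp = scn.bins.loc[shift.change_end, "end"]
        assert abs(start_bp - dup.start) <= 20_000   # +- 2 bins
        assert abs(end_bp - dup.end) <= 20_000
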