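"""VP-SOI partitioning, resampled null, and z-score classification."""

from __future__ import annotations

import numpy as np
import pytest

from m3c import (
    BinGrid,
    FragmentChain,
    ReadPartition,
    VPSOIConfig,
    compute_zscores,
    digest_genome,
    partition_reads,
    positive_profile,
    resample_negative_profile,
    run_vpsoi,
)
from m3c.enzyme import RestrictionEnzyme
from m3c.vpsoi import excluded_bins

from ._oracles import enumerate_negative_profile


@pytest.fixture(scope="module")
def line_map():
    """Uniform 10 bp fragments; one fragment per bin at resolution 10."""
    enz = RestrictionEnzyme("uniform", "GGGG", 4)
    return digest_genome({"chrL": ("ACGTAC" + "GGGG") * 12}, enz)


def _grid():
    return BinGrid("chrL", 0, 120, 10)


def _chain(members, vp=0, rid="r"):
    return FragmentChain(rid, vp, tuple(members), ("+",) * len(members))


def _config(line_map, soi=(50, 60), **kw):
    return VPSOIConfig(0, ("chrL", *soi), _grid(), **kw)


class TestPartition:
    def test_membership_by_member_midpoint_in_soi(self, line_map):
        cfg = _config(line_map)
        chains = [
            _chain([5, 9], rid="a"),  # fragment 5 midpoint 55 in [50,60)
            _chain([9], rid="b"),
            _chain([5], rid="c"),
        ]
        part = partition_reads(chains, line_map, cfg)
        assert [c.read_id for c in part.positive] == ["a", "c"]
        assert [c.read_id for c in part.negative] == ["b"]

    def test_soi_overlapping_viewpoint_rejected(self, line_map):
        cfg = _config(line_map, soi=(0, 10))
        with pytest.raises(ValueError, match="viewpoint"):
            partition_reads([_chain([5])], line_map, cfg)

    def test_unhit_soi_gives_empty_positive_set(self, line_map):
        cfg = _config(line_map)
        part = partition_reads([_chain([9])], line_map, cfg)
        assert part.positive == []
        with pytest.raises(ValueError, match="no VP-SOI"):
            positive_profile(part, line_map, cfg)


class TestPositiveProfile:
    def test_presence_fraction_per_bin(self, line_map):
        cfg = _config(line_map)
        part = ReadPartition(
            positive=[
                _chain([5, 3], rid="a"),
                _chain([5, 3], rid="b"),
                _chain([5], rid="c"),
            ],
            negative=[],
        )
        freq = positive_profile(part, line_map, cfg)
        assert freq[3] == pytest.approx(2 / 3)  # fragment 3 -> bin 3
        assert freq[5] == pytest.approx(1.0)  # SOI bin (later excluded)
        assert freq[8] == 0.0

    def test_viewpoint_and_soi_bins_flagged_excluded(self, line_map):
        cfg = _config(line_map)
        mask = excluded_bins(line_map, cfg)
        assert mask[0] and mask[5]
        assert not mask[3] and not mask[8]


class TestResampledNull:
    def test_two_read_enumeration_oracle(self, line_map):
        """Resampled null converges on the exact removal enumeration.

        Negative reads {A,B} and {A,C} sampled exhaustively (2 from 2):
        the four equally likely removal outcomes give freq(A) in
        {0, 1/2, 1/2, 1} -> mean 0.5, population sd sqrt(0.125).
        """
        cfg = _config(line_map, n_iterations=1000, seed=5)
        A, B, C = 3, 8, 9
        part = ReadPartition(
            positive=[_chain([5], rid="p1"), _chain([5], rid="p2")],
            negative=[_chain([A, B], rid="n1"), _chain([A, C], rid="n2")],
        )
        mean, sd = resample_negative_profile(part, line_map, cfg)
        exact_mean, exact_sd = enumerate_negative_profile(
            [[A, B], [A, C]], cfg.grid.n_bins
        )
        assert exact_mean[A] == pytest.approx(0.5)
        assert exact_sd[A] == pytest.approx(np.sqrt(0.125))
        # 3 standard errors at 1,000 iterations
        se_mean = exact_sd[A] / np.sqrt(1000)
        assert abs(mean[A] - exact_mean[A]) < 3 * se_mean
        mu4 = 0.0625 / 2  # fourth central moment of the removal distribution
        se_sd = np.sqrt(mu4 - exact_sd[A] ** 4) / (2 * exact_sd[A] * np.sqrt(1000))
        assert abs(sd[A] - exact_sd[A]) < 3 * se_sd
        for bin_ in (B, C):
            se = exact_sd[bin_] / np.sqrt(1000)
            assert abs(mean[bin_] - exact_mean[bin_]) < 3 * se + 1e-12

    def test_saturated_bin_has_zero_sd(self, line_map):
        # every negative read touches bin 3 twice: removal cannot empty it
        cfg = _config(line_map, n_iterations=50, seed=1)
        part = ReadPartition(
            positive=[_chain([5], rid="p")],
            negative=[_chain([3, 3, 8], rid="n1"), _chain([3, 3, 9], rid="n2")],
        )
        mean, sd = resample_negative_profile(part, line_map, cfg)
        assert mean[3] == 1.0 and sd[3] == 0.0

    def test_single_iteration_has_zero_sd(self, line_map):
        cfg = _config(line_map, n_iterations=1, seed=2)
        part = ReadPartition(
            positive=[_chain([5], rid="p")],
            negative=[_chain([3, 8], rid="n")],
        )
        _, sd = resample_negative_profile(part, line_map, cfg)
        assert (sd == 0).all()

    def test_small_negative_set_errors_without_replacement(self, line_map):
        cfg = _config(line_map)
        part = ReadPartition(
            positive=[_chain([5], rid="p1"), _chain([5], rid="p2")],
            negative=[_chain([3], rid="n")],
        )
        with pytest.raises(ValueError, match="1 reads.*2 reads"):
            resample_negative_profile(part, line_map, cfg)
        cfg_r = _config(line_map, allow_replacement=True, n_iterations=10)
        mean, _ = resample_negative_profile(part, line_map, cfg_r)
        # the drawn read's sole member is always removed
        assert mean[3] == 0.0

    def test_members_outside_window_are_removable_but_unbinned(self, line_map):
        # member fragment 11 has midpoint 115, outside the [0,120) grid?
        # grid covers [0,120) so use a narrower grid instead
        cfg = VPSOIConfig(0, ("chrL", 50, 60), BinGrid("chrL", 0, 60, 10),
                          n_iterations=200, seed=3)
        part = ReadPartition(
            positive=[_chain([5], rid="p")],
            negative=[_chain([3, 11], rid="n")],
        )
        mean, _ = resample_negative_profile(part, line_map, cfg)
        # removal hits fragment 3 half the time
        assert 0.4 < mean[3] < 0.6


class TestZScores:
    def test_zscore_formula_and_random_label(self, line_map):
        cfg = _config(line_map)
        n = cfg.grid.n_bins
        pos = np.zeros(n)
        mean = np.zeros(n)
        sd = np.ones(n)
        pos[3] = 1.0
        mean[3] = 0.5
        sd[3] = np.sqrt(0.125)
        df = compute_zscores(pos, mean, sd, line_map, cfg)
        assert df.loc[3, "z"] == pytest.approx(1.414, abs=1e-3)
        assert df.loc[3, "label"] == "random"

    def test_threshold_labels(self, line_map):
        cfg = _config(line_map)
        n = cfg.grid.n_bins
        pos = np.zeros(n)
        mean = np.zeros(n)
        sd = np.ones(n)
        pos[3], pos[8] = 2.5, 0.0
        mean[8] = 2.5
        df = compute_zscores(pos, mean, sd, line_map, cfg)
        assert df.loc[3, "label"] == "cooperative"
        assert df.loc[8, "label"] == "competitive"

    def test_zero_sd_sentinels(self, line_map):
        cfg = _config(line_map)
        n = cfg.grid.n_bins
        pos, mean, sd = np.zeros(n), np.zeros(n), np.zeros(n)
        pos[3] = mean[3] = 0.4  # equal -> random, z undefined
        pos[8] = 0.4  # greater -> +inf cooperative
        mean[9], pos[9] = 0.4, 0.0  # smaller -> -inf competitive
        df = compute_zscores(pos, mean, sd, line_map, cfg)
        assert np.isnan(df.loc[3, "z"]) and df.loc[3, "label"] == "random"
        assert np.isposinf(df.loc[8, "z"]) and df.loc[8, "label"] == "cooperative"
        assert np.isneginf(df.loc[9, "z"]) and df.loc[9, "label"] == "competitive"

    def test_excluded_bins_labelled(self, line_map):
        cfg = _config(line_map)
        n = cfg.grid.n_bins
        df = compute_zscores(np.zeros(n), np.zeros(n), np.ones(n), line_map, cfg)
        assert df.loc[0, "label"] == "excluded"  # viewpoint bin
        assert df.loc[5, "label"] == "excluded"  # SOI bin


class TestDeterminism:
    def test_identical_seed_gives_identical_result(self, line_map):
        rng = np.random.default_rng(17)
        chains = []
        for i in range(120):
            members = tuple(
                int(m) for m in rng.choice(np.arange(2, 12), size=rng.integers(1, 4),
                                           replace=False)
            )
            chains.append(_chain(members, rid=f"r{i}"))
        cfg = _config(line_map, n_iterations=100, seed=99)
        r1 = run_vpsoi(chains, line_map, cfg)
        r2 = run_vpsoi(chains, line_map, cfg)
        assert r1.table.equals(r2.table)
        cfg2 = _config(line_map, n_iterations=100, seed=100)
        r3 = run_vpsoi(chains, line_map, cfg2)
        assert not r3.table["negative_mean"].equals(r1.table["negative_mean"])

    def test_tsv_output_uses_sentinel_text(self, line_map, tmp_path):
        cfg = _config(line_map)
        n = cfg.grid.n_bins
        pos, mean, sd = np.zeros(n), np.zeros(n), np.zeros(n)
        pos[8] = 0.4
        df = compute_zscores(pos, mean, sd, line_map, cfg)
        from m3c import VPSOIResult

        res = VPSOIResult(df, cfg, 1, 1)
        path = tmp_path / "vpsoi.tsv"
        res.to_tsv(path)
        text = path.read_text()
        assert "+inf" in text
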