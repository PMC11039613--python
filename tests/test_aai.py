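"""Compartment AAI, SP/CP index, rank correlation and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from stasis_scan.aai import (
    SPCPIndex,
    compute_aai,
    correlate_index_density,
    intragenus_aai,
    species_aai_profile,
    spcp_index,
)
from stasis_scan.records import SpeciesCluster
from stasis_scan.stats import compare_groups

AA = "ACDEFGHIKLMNPQRSTVWY"


def _proteome(rng, n=8, length=60):
    return {
        f"p{i}": "M" + "".join(rng.choice(list(AA), size=length - 1)) for i in range(n)
    }


def _mutate_proteome(rng, proteome, frac):
    out = {}
    for pid, seq in proteome.items():
        arr = list(seq)
        k = round(frac * len(arr))
        for i in rng.choice(len(arr), size=k, replace=False):
            arr[i] = rng.choice([a for a in AA if a != arr[i]])
        out[pid] = "".join(arr)
    return out


class TestComputeAAI:
    def test_identical_proteomes(self, rng):
        prot = _proteome(rng)
        pair = compute_aai(prot, prot)
        assert pair.aai == 100.0
        assert pair.fraction_compared == 1.0
        assert pair.n_rbh == len(prot)

    def test_planted_divergence_recovered(self, rng):
        """5% amino-acid divergence reads out at AAI ~95."""
        prot = _proteome(rng, n=10, length=100)
        mutant = _mutate_proteome(rng, prot, 0.05)
        pair = compute_aai(prot, mutant)
        assert pair.aai == pytest.approx(95.0, abs=0.5)

    def test_fraction_compared_tracks_shared_content(self, rng):
        prot = _proteome(rng, n=12)
        subset = {k: prot[k] for k in list(prot)[:9]}  # remove 25%
        pair = compute_aai(prot, subset)
        assert pair.fraction_compared == pytest.approx(0.75, abs=0.15)
        assert pair.n_rbh == 9

    def test_symmetry(self, rng):
        prot = _proteome(rng, n=6)
        mutant = _mutate_proteome(rng, prot, 0.1)
        assert compute_aai(prot, mutant).aai == pytest.approx(
            compute_aai(mutant, prot).aai, abs=0.1
        )

    def test_empty_proteome_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_aai({}, _proteome(rng))


class TestSpeciesProfile:
    def _cluster_setup(self, rng, n_members, n_sp=3, n_cp=5):
        base_sp = _proteome(rng, n=n_sp)
        base_cp = {f"q{i}": s for i, s in _proteome(rng, n=n_cp).items()}
        proteomes = {}
        compartments = {}
        for m in range(n_members):
            mag = f"m{m}"
            prot = {}
            for pid, seq in {**base_sp, **base_cp}.items():
                key = f"{pid}_{m}"
                prot[key] = seq
                compartments[key] = "SP" if pid.startswith("p") else "CP"
            proteomes[mag] = _mutate_proteome(rng, prot, 0.02)
        cluster = SpeciesCluster(
            cluster_id="c0", members=sorted(proteomes), analysis_eligible=True
        )
        return cluster, proteomes, compartments

    @pytest.mark.parametrize("n_members,n_pairs", [(2, 1), (9, 36), (14, 91)])
    def test_pair_counts_match_binomial_coefficient(self, rng, n_members, n_pairs):
        cluster, proteomes, comps = self._cluster_setup(rng, n_members)
        profile = species_aai_profile(cluster, proteomes, comps)
        counts = profile.groupby("compartment").size()
        assert counts["SP"] == n_pairs
        assert counts["CP"] == n_pairs

    def test_member_without_proteome_excluded(self, rng):
        cluster, proteomes, comps = self._cluster_setup(rng, 3)
        cluster.members.append("ghost")
        with pytest.warns(UserWarning, match="ghost"):
            profile = species_aai_profile(cluster, proteomes, comps)
        assert not profile["mag_a"].str.contains("ghost").any()
        assert not profile["mag_b"].str.contains("ghost").any()


class TestSPCPIndex:
    def _profile(self, sp_vals, cp_vals):
        rows = [{"compartment": "SP", "aai": v} for v in sp_vals]
        rows += [{"compartment": "CP", "aai": v} for v in cp_vals]
        return pd.DataFrame(rows)

    def test_index_is_ratio_of_medians(self):
        idx = spcp_index(
            self._profile([96, 97, 98], [94, 95, 96]),
            coding_density=0.9,
            est_size=1.5e6,
            mean_ani=97.0,
            species_id="sp1",
        )
        assert idx.index == pytest.approx(97 / 95)
        assert idx.size_class == "small"
        assert idx.sp_over_ani == pytest.approx(97 / 97)
        assert idx.cp_over_ani == pytest.approx(95 / 97)

    def test_distance_normalization_mode(self):
        idx = spcp_index(
            self._profile([98], [94]),
            coding_density=0.7,
            est_size=3e6,
            mean_ani=96.0,
            normalize="distance",
        )
        assert idx.sp_over_ani == pytest.approx(2 / 4)
        assert idx.cp_over_ani == pytest.approx(6 / 4)
        assert idx.size_class == "large"

    def test_empty_compartment_rejected(self):
        with pytest.raises(ValueError):
            spcp_index(self._profile([], [95]), 0.9, 1e6, 97.0)


def _indices(pairs):
    return [
        SPCPIndex("s%d" % i, 0, 0, ix, cd, 1e6, "small", 1, 1)
        for i, (ix, cd) in enumerate(pairs)
    ]


class TestCorrelation:
    def test_perfect_monotone(self):
        rho, s, p = correlate_index_density(
            _indices([(0.9, 0.70), (1.0, 0.80), (1.1, 0.90), (1.2, 0.95)])
        )
        assert rho == pytest.approx(1.0)
        assert s == 0.0

    def test_reversed_ranks_closed_form(self):
        # n=5 fully reversed: sum d^2 = 40, rho = -1
        rho, s, p = correlate_index_density(
            _indices([(1.0, 0.95), (1.1, 0.9), (1.2, 0.85), (1.3, 0.8), (1.4, 0.75)])
        )
        assert rho == pytest.approx(-1.0)
        assert s == 40.0

    def test_independent_variables_rarely_correlate(self):
        hits = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            pairs = list(zip(r.random(30), r.random(30)))
            rho, _, _ = correlate_index_density(_indices(pairs))
            hits += abs(rho) < 0.5
        assert hits >= 0.95 * reps

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_index_density(_indices([(1.0, x) for x in (0.7, 0.8, 0.9, 0.95)]))

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            correlate_index_density(_indices([(1.0, 0.7), (1.1, 0.8)]))


class TestCompareGroups:
    def test_identical_distributions_not_significant(self):
        vals = list(np.linspace(0, 1, 20))
        report = compare_groups({"a": vals, "b": vals})
        assert report["p_value"].iloc[0] > 0.9

    def test_planted_shift_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)  # 3 SD shift
        report = compare_groups({"a": list(a), "b": list(b)})
        assert report["p_value"].iloc[0] < 0.001

    def test_three_groups_give_three_pairwise_tests(self, rng):
        groups = {k: list(rng.normal(0, 1, 10)) for k in "abc"}
        report = compare_groups(groups)
        assert (report["test"] == "wilcoxon_rank_sum").sum() == 3
        assert (report["test"] == "kruskal_wallis").sum() == 1

    def test_degenerate_group_excluded_with_warning(self, rng):
        with pytest.warns(UserWarning, match="excluded"):
            report = compare_groups(
                {"a": list(rng.normal(0, 1, 10)), "b": list(rng.normal(0, 1, 10)), "c": [1.0]}
            )
        assert set(report["group_a"]) <= {"a", "(all)"}


class TestIntragenusAAI:
    def _two_species(self, rng, divergence):
        base = _proteome(rng, n=6, length=60)
        prot_a = {f"a_{k}": v for k, v in base.items()}
        prot_b = {
            f"b_{k}": v for k, v in _mutate_proteome(rng, base, divergence).items()
        }
        proteomes = {"A1": prot_a, "B1": prot_b}
        comps = {p: ("SP" if p.split("_")[1].startswith("p0") else "CP")
                 for prot in proteomes.values() for p in prot}
        clusters = [
            SpeciesCluster("spA", ["A1"], analysis_eligible=True),
            SpeciesCluster("spB", ["B1"], analysis_eligible=True),
        ]
        return clusters, proteomes, comps

    def test_identical_species_full_identity(self, rng):
        clusters, proteomes, comps = self._two_species(rng, 0.0)
        df = intragenus_aai({"g1": clusters}, proteomes, comps)
        whole = df[df["compartment"] == "whole"]
        assert (whole["aai"] == 100.0).all()
        assert whole["genus_boundary_ok"].all()

    def test_deep_divergence_fails_genus_boundary(self, rng):
        clusters, proteomes, comps = self._two_species(rng, 0.45)
        df = intragenus_aai({"g1": clusters}, proteomes, comps)
        whole = df[df["compartment"] == "whole"].dropna(subset=["aai"])
        if not whole.empty:
            assert (whole["genus_whole_median_aai"] < 65.0).all()
            assert not whole["genus_boundary_ok"].any()

    def test_singleton_genus_skipped(self, rng):
        clusters, proteomes, comps = self._two_species(rng, 0.1)
        with pytest.warns(UserWarning, match="single species"):
            df = intragenus_aai({"g1": clusters[:1]}, proteomes, comps)
        assert df.empty
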