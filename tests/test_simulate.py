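"""Synthetic genome simulator: determinism, truth labels, map, hit emission."""

import numpy as np
import pandas as pd
import pytest

import armshift as a
from armshift.errors import ValidationError
from armshift.simulate import (
    RecombinationProfile,
    SimulationConfig,
    _3B_LENGTH_BP,
)


def quiet_config(seed=5, **kwargs):
    defaults = dict(
        seed=seed, genes_per_group=60, loss_rate=0.0, duplication_rate=0.0,
        decoy_rate=0.0, terminal_4AS_genes=0, translocated_genes_per_donor=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValidationError):
            SimulationConfig(seed=1, loss_rate=1.5)

    def test_inversion_on_unknown_chromosome(self):
        with pytest.raises(ValidationError):
            SimulationConfig(seed=1, euploid_inversions={"9Z": (0.1, 0.1)})

    def test_artifact_on_3b_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(seed=1, aneuploid_artifacts={"3BS": (0.1, 0.1)})

    def test_negative_recombination_density_rejected(self):
        with pytest.raises(ValidationError):
            RecombinationProfile(suppressed_density=-0.1)

    def test_roundtrip_through_dict(self):
        config = a.default_scenario(3)
        assert SimulationConfig.from_dict(config.to_dict()) == config


class TestSimulateGenome:
    def test_seed_determinism_byte_identical(self):
        c1 = a.default_scenario(42)
        c2 = a.default_scenario(42)
        m1, t1 = a.simulate_genome(c1)
        m2, t2 = a.simulate_genome(c2)
        pd.testing.assert_frame_equal(t1, t2)
        h1, h2 = a.emit_hits(m1), a.emit_hits(m2)
        pd.testing.assert_frame_equal(h1, h2)
        pd.testing.assert_frame_equal(a.genetic_map(m1), a.genetic_map(m2))

    def test_different_seeds_differ(self):
        _, t1 = a.simulate_genome(quiet_config(seed=1, loss_rate=0.5))
        _, t2 = a.simulate_genome(quiet_config(seed=2, loss_rate=0.5))
        assert not t1.equals(t2)

    def test_zero_rearrangement_truth_has_no_moved_genes(self):
        _, truth = a.simulate_genome(quiet_config())
        assert not truth["nonstandard"].any()
        assert not truth["moved_by_euploid_inversion"].any()
        assert not truth["moved_by_aneuploid_artifact"].any()

    def test_conservation_every_gene_has_three_copies(self):
        model, truth = a.simulate_genome(quiet_config(loss_rate=0.1))
        counts = model.copies.groupby("gene").size()
        assert (counts == 3).all()
        assert len(truth) == counts.size

    def test_nested_triple_inversion_emits_exactly_fig3a(self):
        _, truth = a.simulate_genome(a.fig3a_scenario(3))
        patterns = set(truth.loc[truth["nonstandard"], "pattern"])
        assert patterns == {
            "6AS/6BS/6DL", "6AS/6BL/6DL", "6AL/6BS/6DS", "6AL/6BL/6DS"
        }

    def test_euploid_only_configs_never_exceed_four_patterns(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            chroms = [f"6{sg}" for sg in "ABD"][: rng.integers(1, 4)]
            inv = {
                c: (float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.05, 0.4)))
                for c in chroms
            }
            _, truth = a.simulate_genome(
                quiet_config(seed=100 + trial, genes_per_group=150,
                             euploid_inversions=inv)
            )
            group6 = truth[(truth["group"] == 6) & truth["nonstandard"]]
            assert group6["pattern"].nunique() <= 4

    def test_aneuploid_demo_exceeds_bound_and_is_infeasible(self):
        _, truth = a.simulate_genome(a.aneuploid_demo_scenario(3))
        patterns = sorted(set(truth.loc[truth["nonstandard"], "pattern"]))
        assert len(patterns) >= 5
        assert truth["moved_by_aneuploid_artifact"].any()
        assert not a.feasibility_check(patterns).feasible

    def test_unpaired_artifact_creates_both_arm_and_missing_genes(self):
        # an artifact in only one telosome line duplicates pericentromeric
        # genes into both libraries or drops them from both
        config = quiet_config(aneuploid_artifacts={"2BS": (0.4, 0.4)})
        model, truth = a.simulate_genome(config)
        g2 = truth[truth["group"] == 2]
        assert g2["both_arms"].any()
        assert g2["incomplete"].any()
        assert not g2["nonstandard"].any()  # no clean new triplets
        # the classifier excludes exactly those genes
        res = a.classify_all(a.emit_hits(model), genes=list(truth["gene"]))
        merged = truth.merge(res.patterns, on="gene")
        assert (
            merged.loc[merged["both_arms"], "status"] == "excluded_both_arms"
        ).all()
        assert (
            merged.loc[merged["incomplete"], "status"] == "excluded_incomplete"
        ).all()

    def test_translocated_genes_are_excluded_not_misclassified(self):
        config = quiet_config(translocated_genes_per_donor=6)
        model, truth = a.simulate_genome(config)
        res = a.classify_all(a.emit_hits(model), genes=list(truth["gene"]))
        merged = truth.merge(res.patterns, on="gene")
        tr = merged[merged["translocated"]]
        assert len(tr) == 12
        assert (tr["status"] == "excluded_top3_not_homoeologous").all()

    def test_terminal_4AS_genes_show_the_short_set_pattern(self):
        config = quiet_config(terminal_4AS_genes=5)
        _, truth = a.simulate_genome(config)
        term = truth[truth["structural_4A"]]
        assert (term["pattern"] == "4AS/4BS/4DS").all()
        assert (term["transfer"] == "4AL->4AS").all()


class TestGeneticMap:
    def test_uniform_profile_proportional_to_position(self):
        model, _ = a.simulate_genome(quiet_config())
        profile = RecombinationProfile(suppressed_fraction=0.3,
                                       suppressed_density=1.0, distal_density=1.0)
        gmap = a.genetic_map(model, profile)
        live = model.copies[~model.copies["lost"]]
        cen = model.centromere_mb
        L = model.config.chromosome_length_mb
        arm_len = np.where(live["arm_euploid"] == "S", cen, L - cen)
        pos = np.where(
            live["arm_euploid"] == "S",
            cen - live["depth"] * arm_len,
            cen + live["depth"] * arm_len,
        )
        expected = model.config.genetic_length_cm * pos / L
        merged = live.assign(expected=expected).merge(
            gmap, on=["gene", "chromosome"]
        )
        assert np.allclose(merged["cM"], merged["expected"], atol=1e-3)

    def test_suppressed_pericentromere_collapses_map_positions(self):
        model, _ = a.simulate_genome(quiet_config(genes_per_group=120))
        gmap = a.genetic_map(model)
        live = model.copies[~model.copies["lost"]]
        peri = live[live["depth"] < model.config.recombination.suppressed_fraction]
        merged = peri.merge(gmap, on=["gene", "chromosome"])
        for _, grp in merged.groupby("chromosome"):
            assert grp["cM"].max() - grp["cM"].min() <= 2.0

    def test_monotone_in_physical_position(self):
        model, _ = a.simulate_genome(quiet_config())
        gmap = a.genetic_map(model)
        live = model.copies[~model.copies["lost"]].merge(
            gmap, on=["gene", "chromosome"]
        )
        one = live[live["chromosome"] == "5B"].copy()
        cen = model.centromere_mb
        L = model.config.chromosome_length_mb
        arm_len = np.where(one["arm_euploid"] == "S", cen, L - cen)
        one["pos"] = np.where(
            one["arm_euploid"] == "S",
            cen - one["depth"] * arm_len,
            cen + one["depth"] * arm_len,
        )
        one = one.sort_values("pos")
        assert one["cM"].is_monotonic_increasing

    def test_moved_genes_satisfy_comap(self):
        config = quiet_config(euploid_inversions={"2B": (0.15, 0.15)},
                              genes_per_group=150)
        model, truth = a.simulate_genome(config)
        res = a.classify_all(a.emit_hits(model), genes=list(truth["gene"]))
        calls = a.call_all(res.patterns, a.genetic_map(model))
        row = calls.set_index("chromosome").loc["2B"]
        assert row["comap_satisfied"] and row["class"] == "strong"


class TestEmitHits:
    def test_zero_noise_end_to_end_oracle(self, fig3a_run):
        _, truth, _, result = fig3a_run
        classified = set(
            result.patterns.loc[
                result.patterns["classification"] == "nonstandard", "gene"
            ]
        )
        assert classified == set(truth.loc[truth["nonstandard"], "gene"])

    def test_duplication_rate_one_gives_extra_hits(self):
        config = quiet_config(duplication_rate=1.0)
        model, _ = a.simulate_genome(config)
        hits = a.emit_hits(model)
        assert (hits.groupby("qseqid").size() >= 4).all()

    def test_loss_rate_one_leaves_no_hits(self):
        config = quiet_config(loss_rate=1.0)
        model, truth = a.simulate_genome(config)
        assert a.emit_hits(model).empty
        res = a.classify_all(a.emit_hits(model), genes=list(truth["gene"]))
        assert (res.patterns["status"] == "excluded_incomplete").all()

    def test_3b_positions_respect_the_centromere_interval(self):
        model, _ = a.simulate_genome(quiet_config())
        hits = a.emit_hits(model)
        h3b = hits[hits["sseqid"] == "3B"]
        assert not h3b.empty
        mids = (h3b["sstart"] + h3b["send"]) / 2
        cen = a.DEFAULT_3B_CENTROMERE
        assert ((mids < cen.start_bp) | (mids > cen.end_bp)).all()
        assert (h3b["send"] <= _3B_LENGTH_BP).all()

    def test_hits_pass_the_evalue_threshold(self):
        model, _ = a.simulate_genome(quiet_config())
        hits = a.emit_hits(model)
        assert (hits["evalue"] <= 1e-5).all()
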