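"""Footprint quantification: TE, probability inference, flux propagation."""

import random

import numpy as np
import pytest

from rdgkit import (
    FootprintTrack,
    fit_branch_probabilities,
    infer_initiation_probability,
    propagate_flux,
    translation_efficiency,
)
from rdgkit.errors import (
    IdentifiabilityError,
    TooShortError,
    UndefinedProbabilityError,
)
from rdgkit.quantify import node_flux
from rdgkit.simulate import fixture_rdg


def _uniform_track(rdg, translon_id, per_codon=1.0):
    counts = np.zeros(len(rdg.transcript.seq))
    for cpos in rdg.translons[translon_id].codon_starts():
        counts[cpos - 1] += per_codon
    return FootprintTrack(rdg.transcript.id, counts)


class TestTranslationEfficiency:
    def test_uniform_density_gives_one_footprint_per_codon(self, chain2):
        track = _uniform_track(chain2, "T1")
        te = translation_efficiency(track, chain2.translons["T1"], rdg=chain2)
        assert te == pytest.approx(1.0)

    def test_counts_in_first_five_codons_are_ignored(self, chain2):
        t1 = chain2.translons["T1"]
        counts = np.zeros(len(chain2.transcript.seq))
        for cpos in t1.codon_starts()[:5]:
            counts[cpos - 1] = 1000
        track = FootprintTrack(chain2.transcript.id, counts)
        assert translation_efficiency(track, t1, rdg=chain2) == 0.0

    def test_counts_outside_the_translon_are_ignored(self, chain2):
        t1 = chain2.translons["T1"]
        counts = np.ones(len(chain2.transcript.seq)) * 7  # background everywhere
        base = FootprintTrack(chain2.transcript.id, counts)
        ref = translation_efficiency(base, t1, rdg=chain2)
        counts2 = counts.copy()
        counts2[:3] += 1000  # 5' leader
        counts2[-3:] += 1000  # trailer
        boosted = FootprintTrack(chain2.transcript.id, counts2)
        assert translation_efficiency(boosted, t1, rdg=chain2) == ref

    def test_exclusive_only_removes_shared_positions(self, gpx4):
        # readthrough translon shares its 5' part with the short one;
        # exclusive TE of the long translon uses only the extension
        t_long = next(t for t in gpx4.translons.values() if t.events)
        track = _uniform_track(gpx4, t_long.id)
        te_excl = translation_efficiency(track, t_long, rdg=gpx4)
        te_all = translation_efficiency(track, t_long, exclusive_only=False)
        assert te_excl == pytest.approx(1.0)
        assert te_all == pytest.approx(1.0)

    def test_too_short_translon_rejected(self, chain2):
        track = _uniform_track(chain2, "T1")
        assert chain2.translons["T1"].n_codons == 35
        with pytest.raises(TooShortError):
            translation_efficiency(
                track, chain2.translons["T1"], rdg=chain2, trim_codons=35
            )

    def test_te_by_direct_position_sum(self, chain2):
        """Oracle: direct summation over the retained positions."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, len(chain2.transcript.seq)).astype(float)
        track = FootprintTrack(chain2.transcript.id, counts)
        t1 = chain2.translons["T1"]
        retained = t1.codon_starts()[5:]
        expected = sum(
            counts[p - 1] + counts[p] + counts[p + 1] for p in retained
        ) / len(retained)
        got = translation_efficiency(track, t1, rdg=chain2)
        assert got == pytest.approx(expected)


class TestInferProbability:
    def test_methods_formula(self):
        assert infer_initiation_probability(3, 1) == pytest.approx(0.75)
        assert infer_initiation_probability(2, 2) == pytest.approx(0.5)
        assert infer_initiation_probability(5, 0) == 1.0

    def test_no_flux_is_undefined(self):
        with pytest.raises(UndefinedProbabilityError):
            infer_initiation_probability(0, 0)

    def test_monotone_in_upstream_te(self):
        probs = [infer_initiation_probability(ru, 2.0) for ru in np.linspace(0, 9, 30)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))


class TestPropagateFlux:
    def test_two_outcome_split(self, chain2):
        res = propagate_flux(chain2, {"start@4": 0.8, "start@115": 1.0})
        assert res.translon_flux["T1"] == pytest.approx(0.8)
        assert res.translon_flux["T2"] == pytest.approx(0.2)

    def test_full_upstream_initiation_silences_downstream(self, chain2):
        res = propagate_flux(chain2, {"start@4": 1.0, "start@115": 1.0})
        assert res.translon_flux["T2"] == 0.0

    def test_path_probabilities_match_per_path_products(self, fig3):
        rng = random.Random(13)
        p = {n: rng.random() for n in fig3.branch_nodes()}
        res = propagate_flux(fig3, p)
        assert sum(res.path_prob.values()) == pytest.approx(1.0, abs=1e-12)
        from rdgkit import enumerate_paths

        for path in enumerate_paths(fig3):
            assert res.path_prob[path.id] == pytest.approx(path.probability)

    def test_flux_is_conserved_at_every_node(self, fig3):
        fig3.set_branch_probabilities(
            {n: 0.3 for n in fig3.branch_nodes()}
        )
        flux = node_flux(fig3)
        g = fig3.graph
        for node in g.nodes:
            inflow = sum(d["flux"] for _, _, d in g.in_edges(node, data=True))
            outflow = sum(d["flux"] for _, _, d in g.out_edges(node, data=True))
            if node == ("cap",):
                assert outflow == pytest.approx(1.0)
            elif g.out_degree(node) == 0:
                continue
            else:
                assert inflow == pytest.approx(outflow)
        sinks = [n for n in g.nodes if g.out_degree(n) == 0]
        assert sum(
            d["flux"] for n in sinks for _, _, d in g.in_edges(n, data=True)
        ) == pytest.approx(1.0)

    def test_missing_probability_raises(self, fig3):
        for node in fig3.branch_nodes():
            for _, _, d in fig3.graph.out_edges(node, data=True):
                d.pop("p", None)
        with pytest.raises(ValueError, match="without probabilities"):
            propagate_flux(fig3)

    def test_relative_synthesis_sums_to_100(self, fig3):
        res = propagate_flux(fig3, {"start@2": 0.4, "start@10": 0.2, "start@19": 0.7})
        assert sum(res.rel_synthesis.values()) == pytest.approx(100.0)


class TestFitBranchProbabilities:
    def test_two_translon_chain_equals_methods_formula(self, chain2):
        te = {"T1": 3.0, "T2": 1.0}
        p = fit_branch_probabilities(chain2, te)
        assert p["start@4"] == pytest.approx(
            infer_initiation_probability(3.0, 1.0)
        )
        assert p["start@115"] == 1.0

    def test_equal_te_three_chain_closed_form(self):
        rdg = fixture_rdg("leaky_chain", k=3)
        p = fit_branch_probabilities(rdg, {"T1": 5.0, "T2": 5.0, "T3": 5.0})
        vals = [p[k] for k in sorted(p, key=lambda s: int(s.split("@")[1]))]
        assert vals == pytest.approx([1 / 3, 1 / 2, 1.0])

    def test_noiseless_round_trip_on_fig3(self, fig3):
        truth = {"start@2": 0.31, "start@10": 0.57, "start@19": 0.83}
        res = propagate_flux(fig3, truth)
        fitted = fit_branch_probabilities(
            fig3, res.translon_flux, fix_terminal=False, scale=1.0
        )
        for key, val in truth.items():
            assert fitted[key] == pytest.approx(val, abs=1e-6)

    def test_fit_propagate_identity_on_chain(self, chain2):
        for p_true in (0.05, 0.4, 0.95):
            res = propagate_flux(chain2, {"start@4": p_true, "start@115": 1.0})
            fitted = fit_branch_probabilities(chain2, res.translon_flux)
            assert fitted["start@4"] == pytest.approx(p_true, abs=1e-12)

    def test_monotonicity_of_fitted_probability(self, chain2):
        fits = [
            fit_branch_probabilities(chain2, {"T1": ru, "T2": 2.0})["start@4"]
            for ru in np.linspace(0.1, 8.0, 15)
        ]
        assert all(b >= a for a, b in zip(fits, fits[1:]))

    def test_non_identifiable_configuration_raises(self, fig3):
        # only one observed TE for three free branches
        with pytest.raises(IdentifiabilityError):
            fit_branch_probabilities(
                fig3, {"T1": 1.0, "T2": 1.0, "T3": 1.0},
                fix_terminal=False, scale=None,
            )


def test_track_io_round_trip(tmp_path, chain2):
    from rdgkit import read_track, simulate_track, write_track_bedgraph
    from rdgkit.simulate import SimConfig

    track = simulate_track(
        chain2, {"start@4": 0.5, "start@115": 1.0}, SimConfig(seed=1)
    )
    path = tmp_path / "t.bedgraph"
    write_track_bedgraph(track, path)
    back = read_track(path, length=len(track))
    assert np.array_equal(back.counts, track.counts)
    # TSV form
    tsv = tmp_path / "t.tsv"
    tsv.write_text(
        "".join(
            f"{i + 1}\t{int(c)}\n" for i, c in enumerate(track.counts) if c
        )
    )
    back2 = read_track(tsv, length=len(track))
    assert np.array_equal(back2.counts, track.counts)
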