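"""Ion filtering, neutral-mass clustering and ppm matching."""

import random

import pytest

from venomics.chemistry import ToxinRecord, mz_from_mass
from venomics.validation import (
    PrecursorIon,
    cluster_ions,
    filter_ions,
    match_toxins,
    ppm_error,
    theoretical_ladder,
)


def ion(mass, z, intensity=1e6, rt=10.0):
    return PrecursorIon(mz_from_mass(mass, z), z, intensity, rt, "run1")


class TestFilterIons:
    def test_strictly_below_threshold_excluded(self):
        ions = [ion(1000, 2, 4.9e5), ion(1000, 2, 5.0e5), ion(1000, 2, 5.1e5)]
        kept = filter_ions(ions)
        assert [i.intensity for i in kept] == [5.0e5, 5.1e5]

    def test_empty_input_empty_output(self):
        assert filter_ions([]) == []

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            filter_ions([ion(1000, 2), PrecursorIon(500.0, 2, -1.0)])

    def test_order_preserved(self):
        ions = [ion(m, 2, 1e6) for m in (3000, 1000, 2000)]
        assert [i.mz for i in filter_ions(ions)] == [i.mz for i in ions]


class TestClusterIons:
    def test_charge_states_of_one_mass_merge(self):
        clusters = cluster_ions([ion(3690.489, 4), ion(3690.489, 5)])
        assert len(clusters) == 1
        assert clusters[0].neutral_mass == pytest.approx(3690.489, abs=1e-3)
        assert clusters[0].charges == {4, 5}

    def test_masses_100_ppm_apart_stay_separate(self):
        clusters = cluster_ions([ion(1000.000, 1), ion(1000.100, 1)])
        assert len(clusters) == 2

    def test_singleton(self):
        clusters = cluster_ions([ion(1234.5, 2)])
        assert len(clusters) == 1 and len(clusters[0].members) == 1

    def test_partition_no_ion_lost_or_duplicated(self):
        rng = random.Random(3)
        ions = [
            ion(rng.uniform(800, 8000), rng.randint(1, 6), rng.uniform(1e5, 1e7))
            for _ in range(200)
        ]
        clusters = cluster_ions(ions)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(ions)
        assert {id(m) for m in members} == {id(i) for i in ions}

    def test_invariant_to_input_order(self):
        rng = random.Random(4)
        ions = [ion(rng.uniform(800, 8000), rng.randint(2, 5)) for _ in range(50)]
        shuffled = ions[:]
        rng.shuffle(shuffled)
        key = lambda cs: sorted(
            (round(c.neutral_mass, 6), len(c.members)) for c in cs if c.clustered
        )
        assert key(cluster_ions(ions)) == key(cluster_ions(shuffled))

    def test_unknown_charge_passes_through_unclustered(self):
        unknown = PrecursorIon(500.0, 0, 1e6)
        clusters = cluster_ions([ion(1000, 2), unknown])
        flags = sorted(c.clustered for c in clusters)
        assert flags == [False, True]
        passthrough = next(c for c in clusters if not c.clustered)
        assert passthrough.neutral_mass is None

    def test_redundant_intensity_summed_by_default_dropped_on_flag(self):
        ions = [ion(2000.0, 2, 1e6), ion(2000.0, 3, 2e6)]
        merged = cluster_ions(ions)[0]
        assert merged.total_intensity == pytest.approx(3e6)
        dropped = cluster_ions(ions, drop_redundant=True)[0]
        assert len(dropped.members) == 1
        assert dropped.total_intensity == pytest.approx(2e6)


class TestTheoreticalLadder:
    def test_default_ladder_has_eight_charges(self):
        ladder = theoretical_ladder(3690.489)
        assert [z for z, _ in ladder] == list(range(2, 10))
        mzs = [mz for _, mz in ladder]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))

    def test_doubly_charged_value(self):
        assert theoretical_ladder(3690.489)[0][1] == pytest.approx(1846.252, abs=1e-3)

    def test_single_charge_ladder(self):
        ladder = theoretical_ladder(1000.0, 1, 1)
        assert ladder == [(1, pytest.approx(1001.00727646))]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            theoretical_ladder(1000.0, 3, 2)


class TestMatchToxins:
    TOXIN = ToxinRecord("U1-TRTX-Agm3a", "ACGSFMWKCSERLPCCQEYVCSPQWKWCQNP", 3)

    def test_close_cluster_matches_within_tolerance(self):
        clusters = cluster_ions([ion(3690.48, 3)])
        (report,) = match_toxins([self.TOXIN], clusters)
        assert report.validated
        assert abs(report.best_ppm_error) < 10

    def test_distant_cluster_does_not_match(self):
        clusters = cluster_ions([ion(3691.489, 3)])
        (report,) = match_toxins([self.TOXIN], clusters)
        assert not report.validated and report.matched_charges == set()

    def test_msms_support_required_for_validation(self):
        clusters = cluster_ions([ion(3690.489, 3)])
        (report,) = match_toxins(
            [self.TOXIN], clusters, msms_supported={"U1-TRTX-Agm3a": False}
        )
        assert report.matched_charges and not report.validated
        (relaxed,) = match_toxins(
            [self.TOXIN],
            clusters,
            require_msms=False,
            msms_supported={"U1-TRTX-Agm3a": False},
        )
        assert relaxed.validated

    def test_singly_charged_ion_cannot_trigger_validation(self):
        clusters = cluster_ions([ion(3690.489, 1)])
        (report,) = match_toxins([self.TOXIN], clusters)
        assert not report.validated

    def test_every_toxin_yields_one_report(self):
        toxins = [self.TOXIN, ToxinRecord("short", "VPPILKY")]
        reports = match_toxins(toxins, cluster_ions([ion(828.5109, 2)]))
        assert [r.toxin_id for r in reports] == ["U1-TRTX-Agm3a", "short"]
        assert reports[1].validated and not reports[0].validated

    def test_ppm_reference_is_theoretical_mass(self):
        assert ppm_error(1000.01, 1000.0) == pytest.approx(10.0)
        # flipping the reference changes the error only at second order
        assert abs(ppm_error(1000.01, 1000.0) + ppm_error(1000.0, 1000.01)) < 0.01
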