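"""Synthetic cohort generator: determinism, design, planted effects."""

import dataclasses

import numpy as np
import pytest

from taskfc.cohort import (
    CohortSpec,
    CouplingEffect,
    CueTiming,
    MidTiming,
    NETWORKS,
    StateSequenceParams,
    default_geometry,
    default_partition,
    generate_cohort,
    generate_events,
    generate_receptor_map,
)
from taskfc.mifc import mifc_matrix


class TestSpecValidation:
    def test_study_sized_cohort_has_47_subjects(self, small_cohort):
        spec = CohortSpec(seed=0)
        assert spec.n_subjects == 47
        assert len(small_cohort.subjects) == 6  # fixture sanity

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(n_group_a=0), "positive"),
            (dict(n_regions=-3), "positive"),
            (dict(coupling_effects=(CouplingEffect(("vmn", "control"), "A", -1.0),)),
             "gain"),
            (dict(coupling_effects=(CouplingEffect(("vmn", "nosuch"), "A", 2.0),)),
             "unknown network"),
            (dict(n_volumes={"mid": 30, "cue": 220}), "shorter"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, match):
        with pytest.raises((ValueError, TypeError), match=match):
            CohortSpec(seed=1, **kwargs)

    def test_seed_is_mandatory(self):
        with pytest.raises((ValueError, TypeError)):
            CohortSpec(seed=None)


class TestPartitionAndGeometry:
    @pytest.mark.parametrize("n_regions", [50, 214])
    def test_partition_invariants(self, n_regions):
        part = default_partition(n_regions)
        assert part.membership.any(axis=1).all()      # every region labelled
        assert part.membership.any(axis=0).all()      # all 9 networks non-empty
        assert part.membership.shape == (n_regions, 9)
        # VMN overlaps cortical membership
        vmn = part.membership[:, NETWORKS.index("vmn")]
        cortical_nets = part.membership[:, :8].any(axis=1)
        assert (vmn & cortical_nets).any()

    @pytest.mark.parametrize("n_regions", [50, 214])
    def test_geometry_invariants(self, n_regions):
        geom = default_geometry(n_regions)
        norms = np.linalg.norm(geom.coords[geom.is_cortical], axis=1)
        assert np.allclose(norms, 1.0)
        assert (np.linalg.norm(geom.coords[~geom.is_cortical], axis=1) < 1).all()
        left = (geom.hemisphere == "L").sum()
        assert left == (geom.hemisphere == "R").sum()


class TestEvents:
    def test_cue_blocks_alternate(self):
        ev = generate_events("cue", CueTiming(n_blocks_per_condition=6))
        labels = ev.condition.astype(str)
        assert len(labels) == 12
        assert list(labels[::2]) == ["drug"] * 6
        assert list(labels[1::2]) == ["neutral"] * 6
        assert (ev.duration == 20.0).all()

    def test_mid_anticipations_drawn_evenly(self):
        ev = generate_events("mid", MidTiming(n_trials=30), seed=1)
        labels = ev.condition.astype(str)
        ant = labels[np.char.endswith(labels, "anticipation")]
        assert len(ant) == 30
        for kind in ("reward", "neutral", "loss"):
            assert (np.char.startswith(ant, kind)).sum() == 10

    def test_onsets_increase_and_fit_acquisition(self):
        for seed in range(100):
            n_trials = 12 + (seed % 20) * 3
            timing = MidTiming(n_trials=n_trials)
            ev = generate_events("mid", timing, seed=seed)
            assert np.all(np.diff(ev.onset) >= 0)
            assert (ev.duration > 0).all()
            n_vol = int(np.ceil(timing.total_seconds / 2.0))
            assert ev.span <= n_vol * 2.0 + 1e-9


class TestReceptorMaps:
    def test_white_noise_limit_uncorrelated(self):
        # 100 draws: the sampling floor of mean |r| for independent values
        # is ~0.08, so the 0.1 bound discriminates real spatial coupling
        geom = default_geometry(40)
        draws = np.stack([
            generate_receptor_map(geom, autocorr_length=1e-3, seed=s)
            for s in range(100)
        ])
        corr = np.corrcoef(draws.T)
        iu = np.triu_indices(40, 1)
        assert np.abs(corr[iu]).mean() < 0.1

    def test_vmn_enrichment_forced(self):
        geom = default_geometry(60)
        part = default_partition(60)
        vmn = part.membership[:, NETWORKS.index("vmn")]
        vals = generate_receptor_map(geom, 0.5, vmn_enrichment=3.0,
                                     seed=3, vmn_mask=vmn)
        assert vals[vmn].mean() > vals[~vmn].mean()
        assert (vals >= 0).all()

    def test_spatial_autocorrelation_monotone_in_length_scale(self):
        geom = default_geometry(60)
        d = np.linalg.norm(geom.coords[:, None] - geom.coords[None, :], axis=-1)
        w = (d < 0.6) & (d > 0)  # neighbour weights for a Moran-style index

        def moran(v):
            z = v - v.mean()
            return (w * np.outer(z, z)).sum() / (w.sum() * z.var())

        means = []
        for ell in (0.1, 0.5, 1.0):
            vals = [moran(generate_receptor_map(geom, ell, seed=s))
                    for s in range(50)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_bad_length_scale_rejected(self):
        with pytest.raises(ValueError, match="autocorr"):
            generate_receptor_map(default_geometry(30), 0.0)


class TestGenerateCohort:
    def test_bit_identical_under_same_spec_and_seed(self):
        spec = CohortSpec(seed=42, n_group_a=2, n_group_b=2, n_regions=40,
                          tasks=("cue",))
        a = generate_cohort(spec)
        b = generate_cohort(dataclasses.replace(spec))
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa["data"]["cue"].timeseries.data,
                                  sb["data"]["cue"].timeseries.data)
            assert np.array_equal(sa["data"]["cue"].true_states,
                                  sb["data"]["cue"].true_states)
        for r in a.receptors.values:
            assert np.array_equal(a.receptors.values[r], b.receptors.values[r])

    def test_different_seeds_differ(self):
        base = dict(n_group_a=2, n_group_b=2, n_regions=40, tasks=("cue",))
        a = generate_cohort(CohortSpec(seed=1, **base))
        b = generate_cohort(CohortSpec(seed=2, **base))
        assert not np.array_equal(a.subjects[0]["data"]["cue"].timeseries.data,
                                  b.subjects[0]["data"]["cue"].timeseries.data)

    def test_groups_exchangeable_without_planted_effects(self):
        # Monte-Carlo over replicate null cohorts: the edge-averaged group
        # difference fluctuates around zero within 3x its replicate SE
        deltas = []
        for rep in range(12):
            spec = CohortSpec(seed=900 + rep, n_group_a=2, n_group_b=2,
                              n_regions=30, tasks=("mid",),
                              n_volumes={"mid": 150},
                              mid_timing=MidTiming(n_trials=27))
            coh = generate_cohort(spec)
            iu = np.triu_indices(30, 1)
            mats = [mifc_matrix(s["data"]["mid"].timeseries).values[iu]
                    for s in coh.subjects]
            deltas.append(np.mean(mats[:2], axis=0).mean()
                          - np.mean(mats[2:], axis=0).mean())
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_planted_coupling_raises_between_network_mifc(self):
        # VMN-DMN coupling gain x1.5 in group B lifts the mean miFC over the
        # planted between-network edges in essentially every replicate at
        # the default run length
        wins = 0
        for rep in range(20):
            spec = CohortSpec(
                seed=500 + rep, n_group_a=12, n_group_b=12, n_regions=50,
                tasks=("mid",),
                coupling_effects=(
                    CouplingEffect(("vmn", "default_mode"), "B", 1.5),
                ),
            )
            coh = generate_cohort(spec)
            vmn = set(coh.partition.members("vmn"))
            dmn = set(coh.partition.members("default_mode"))
            edges = [(min(i, j), max(i, j)) for i in vmn - dmn for j in dmn - vmn]
            mats = [mifc_matrix(s["data"]["mid"].timeseries).values
                    for s in coh.subjects]
            mean_a = np.mean([[m[e] for e in edges] for m in mats[:12]])
            mean_b = np.mean([[m[e] for e in edges] for m in mats[12:]])
            wins += mean_b > mean_a
        assert wins >= 19

    def test_ground_truth_states_have_configured_dwells(self, small_cohort):
        truth = small_cohort.subjects[0]["data"]["mid"].true_states
        runs = np.diff(np.flatnonzero(np.diff(truth) != 0))
        # min dwell 10 s = 5 volumes at TR 2 (interior runs only)
        assert runs.min() >= 4
        assert set(truth) <= set(range(9))
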