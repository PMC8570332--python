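"""Symmetry search: symmetrization, scoring, grid search and refinement."""

import math

import numpy as np
import pytest
from scipy import ndimage

from sheathkit import symmetry as sym
from sheathkit import synthesis as syn
from sheathkit.errors import InsufficientOverlapError, UndefinedScoreError

from conftest import MASK_RADIUS, TRUTH


def naive_score(vol, twist_deg, rise_ang, n_copies=5, pg=6, rmask=176.0,
                max_rise=None):
    """Independent copy-by-copy scorer using whole-volume scipy transforms.

    Each screw copy is produced by rotating the full C_n-averaged grid with
    ``scipy.ndimage.rotate`` (cubic spline) and sinc-shifting it along z; the
    score is the mean Pearson correlation of the copies with the raw map
    inside the cylindrical mask.  Deliberately naive: no caching, no masked
    sampling, no shear decomposition.
    """
    grid = vol.grid.astype(np.float64)
    n, c, voxel = vol.box_voxels, vol.center_voxel, vol.voxel_size_ang
    prefold = np.zeros_like(grid)
    for j in range(pg):
        prefold += ndimage.rotate(
            grid, -j * 360.0 / pg, axes=(2, 1), reshape=False, order=3
        )
    prefold /= pg
    ax = (np.arange(n) - c) * voxel
    disk = (ax[None, :] ** 2 + ax[:, None] ** 2) <= rmask**2
    kmax = n_copies // 2
    trim_rise = max_rise if max_rise is not None else rise_ang
    trim = int(math.ceil(kmax * trim_rise / voxel)) + 1
    mask = np.zeros(grid.shape, dtype=bool)
    mask[trim : n - trim] = disk
    raw = grid[mask]
    raw = raw - raw.mean()
    correlations = []
    freqs = np.fft.rfftfreq(n)
    for k in range(-kmax, kmax + 1):
        if k == 0:
            continue
        rot = ndimage.rotate(
            prefold, -k * twist_deg, axes=(2, 1), reshape=False, order=3
        )
        spec = np.fft.rfft(rot, axis=0)
        spec *= np.exp(-2j * np.pi * freqs * (k * rise_ang / voxel))[:, None, None]
        copy = np.fft.irfft(spec, n=n, axis=0)
        v = copy[mask]
        v = v - v.mean()
        correlations.append(
            float(raw @ v) / math.sqrt(float(raw @ raw) * float(v @ v))
        )
    return float(np.mean(correlations))


class TestSymmetrize:
    def test_identity_operation(self, contracted_map):
        out = sym.symmetrize(contracted_map, 27.13, 18.89, n_copies=1,
                             point_group_order=1)
        assert np.array_equal(out.grid, contracted_map.grid)

    def test_true_parameters_change_little(self, contracted_map):
        out, mask = sym.symmetrize(
            contracted_map, 27.13, 18.89, n_copies=5, point_group_order=6,
            mask_radius_ang=MASK_RADIUS["contracted"], return_mask=True,
        )
        a = contracted_map.grid[mask].astype(np.float64)
        b = out.grid[mask].astype(np.float64)
        nrms = np.sqrt(np.mean((a - b) ** 2)) / np.std(a)
        assert nrms < 0.02

    def test_idempotent_up_to_interpolation(self, contracted_map):
        once, mask1 = sym.symmetrize(
            contracted_map, 27.13, 18.89, n_copies=5, point_group_order=6,
            mask_radius_ang=MASK_RADIUS["contracted"], return_mask=True,
        )
        twice, _ = sym.symmetrize(
            once, 27.13, 18.89, n_copies=5, point_group_order=6,
            mask_radius_ang=MASK_RADIUS["contracted"], return_mask=True,
        )
        # compare deep in the interior, away from the masked-out boundary rows
        zz = np.arange(2 * 8, contracted_map.box_voxels - 2 * 8)
        interior = np.zeros_like(mask1)
        interior[zz] = mask1[zz]
        a = once.grid[interior].astype(np.float64)
        b = twice.grid[interior].astype(np.float64)
        nrms = np.sqrt(np.mean((a - b) ** 2)) / np.std(a)
        assert nrms < 0.02

    def test_insufficient_overlap_raises(self, contracted_map):
        with pytest.raises(InsufficientOverlapError):
            sym.symmetrize(contracted_map, 27.13, 500.0, n_copies=5)

    def test_subvoxel_rise_raises(self, contracted_map):
        with pytest.raises(InsufficientOverlapError):
            sym.symmetrize(contracted_map, 27.13, 0.5, n_copies=5)


class TestScore:
    def test_self_score_is_one(self, contracted_map):
        s = sym.score_symmetry(contracted_map, 27.13, 18.89, n_copies=1,
                               point_group_order=1)
        assert s.score == 1.0

    def test_true_parameters_score_high(self, contracted_map):
        s = sym.score_symmetry(contracted_map, 27.13, 18.89,
                               mask_radius_ang=MASK_RADIUS["contracted"])
        assert s.score >= 0.98

    def test_wrong_twist_scores_lower(self, contracted_map):
        ctx = sym.SymmetrySearchContext(
            contracted_map, mask_radius_ang=MASK_RADIUS["contracted"]
        )
        assert ctx.score(37.13, 18.89).score < ctx.score(27.13, 18.89).score

    def test_zero_volume_raises(self):
        vol = syn.DensityVolume(np.zeros((32, 32, 32), dtype=np.float32), 4.0)
        with pytest.raises(UndefinedScoreError):
            sym.score_symmetry(vol, 20.0, 10.0)

    def test_monotone_degradation_along_twist(self, contracted_map):
        ctx = sym.SymmetrySearchContext(
            contracted_map, mask_radius_ang=MASK_RADIUS["contracted"]
        )
        scores = [ctx.score(27.13 + d, 18.89).score for d in range(6)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_mirror_handedness_invariance(self, contracted_map):
        mirrored = syn.DensityVolume(
            np.ascontiguousarray(contracted_map.grid[:, :, ::-1]),
            contracted_map.voxel_size_ang,
        )
        for t, r in [(27.13, 18.89), (25.0, 20.0)]:
            right = sym.score_symmetry(
                contracted_map, t, r, handedness="right",
                mask_radius_ang=MASK_RADIUS["contracted"],
            ).score
            left = sym.score_symmetry(
                mirrored, t, r, handedness="left",
                mask_radius_ang=MASK_RADIUS["contracted"],
            ).score
            assert left == pytest.approx(right, abs=1e-9)


class TestGridSearch:
    def test_single_cell(self, contracted_map):
        surf = sym.grid_search(contracted_map, (27.13, 27.13), 1.0,
                               (18.89, 18.89), 1.0,
                               mask_radius_ang=MASK_RADIUS["contracted"])
        assert surf.scores.shape == (1, 1)
        assert (surf.argmax.twist_deg, surf.argmax.rise_ang) == (27.13, 18.89)

    @pytest.mark.parametrize("state,twist_range,rise_range", [
        ("contracted", (20.0, 35.0), (14.0, 24.0)),
        ("non_contracted", (15.0, 25.0), (36.0, 46.0)),
    ])
    def test_argmax_within_half_step_of_truth(self, request, state,
                                              twist_range, rise_range):
        vol = request.getfixturevalue(
            "contracted_map" if state == "contracted" else "nc_map"
        )
        surf = sym.grid_search(vol, twist_range, 0.5, rise_range, 0.5,
                               mask_radius_ang=MASK_RADIUS[state])
        t0, r0 = TRUTH[state]
        assert abs(surf.argmax.twist_deg - t0) <= 0.25 + 1e-9
        assert abs(surf.argmax.rise_ang - r0) <= 0.25 + 1e-9

    def test_matches_naive_oracle(self):
        vol = syn.simulate_sheath_map("contracted", box_voxels=64, snr=1.0, seed=42)
        rmask = MASK_RADIUS["contracted"]
        twists = np.arange(25.13, 29.14, 1.0)
        rises = np.arange(16.89, 20.90, 1.0)
        surf = sym.grid_search(vol, (twists[0], twists[-1]), 1.0,
                               (rises[0], rises[-1]), 1.0,
                               mask_radius_ang=rmask)
        oracle = np.array(
            [[naive_score(vol, t, r, rmask=rmask, max_rise=rises[-1])
              for r in rises] for t in twists]
        )
        oi, oj = np.unravel_index(np.argmax(oracle), oracle.shape)
        assert (surf.argmax.twist_deg, surf.argmax.rise_ang) == (
            pytest.approx(twists[oi]), pytest.approx(rises[oj])
        )
        assert np.allclose(surf.scores, oracle, atol=0.02)


class TestRefine:
    def test_fixed_point_at_truth(self, contracted_map):
        ctx = sym.SymmetrySearchContext(
            contracted_map, mask_radius_ang=MASK_RADIUS["contracted"],
            max_rise_ang=24.0,
        )
        start = ctx.score(27.13, 18.89)
        best = sym.refine(contracted_map, start, tol=0.02, context=ctx)
        assert abs(best.twist_deg - 27.13) <= 0.1
        assert abs(best.rise_ang - 18.89) <= 0.1

    def test_recovers_from_offset_start(self, nc_map):
        ctx = sym.SymmetrySearchContext(
            nc_map, mask_radius_ang=MASK_RADIUS["non_contracted"],
            max_rise_ang=46.0,
        )
        start = ctx.score(20.57 + 0.4, 41.53 + 0.4)
        best = sym.refine(nc_map, start, tol=0.02, context=ctx)
        assert abs(best.twist_deg - 20.57) <= 0.1
        assert abs(best.rise_ang - 41.53) <= 0.1

    def test_never_worse_than_start(self, contracted_map):
        ctx = sym.SymmetrySearchContext(
            contracted_map, mask_radius_ang=MASK_RADIUS["contracted"],
            max_rise_ang=24.0,
        )
        start = ctx.score(26.0, 18.0)
        best = sym.refine(contracted_map, start, tol=0.05, context=ctx)
        assert best.score >= start.score
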