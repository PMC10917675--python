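"""Synthetic phantom cohorts with known dysfunctional targets.

The generator emulates the statistical structure the mapping methods
rely on, without any patient data: bilateral four-contact electrodes
implanted near a small phantom nucleus with random placement jitter,
analytic monotonically decaying E-field magnitudes, bundles of smooth
streamlines coursing through the stimulated region, and outcomes that
equal planted-target engagement plus noise.

The E-field is an inverse-square point-source profile — a stand-in that
preserves the monotone spatial decay of a stimulation field, not a
physics claim.  It is calibrated so a 2 mA single-contact field crosses
200 V/m (the usual axonal activation estimate) at 3.5 mm.

Every random quantity flows from one master seed through spawned
generators, so a cohort is bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, PatientRecord
from .imaging import (
    EFieldVolume,
    StreamlineSet,
    VoxelVolume,
    save_streamlines,
    save_volume,
)

__all__ = [
    "PhantomScene",
    "SimulationTruth",
    "make_scene",
    "make_bundles",
    "simulate_efield",
    "make_cohort",
    "noise_sd_for_fraction",
]

# Field calibration: kappa * 2 mA / 3.5 mm^2 = 200 V/m.
FIELD_KAPPA = 200.0 * 3.5**2 / 2.0      # V/m * mm^2 / mA
FIELD_CORE_RADIUS_MM = 0.5              # caps the point-source singularity

DEFAULT_BASELINE_SCORE = 40.0           # synthetic severity scale points
CONTACT_SPACING_MM = 2.0                # 4-contact linear lead
STANDARD_CONTACT = 1                    # second-to-lowest contact is active


@dataclass
class SimulationTruth:
    """Ground truth planted into a synthetic cohort."""

    target_kind: str                       # "spot" | "bundle"
    planted_spot_center: np.ndarray | None = None   # mm, left hemisphere
    planted_bundle: str | None = None
    effect_size: float = 15.0              # improvement points per engagement SD
    noise_sd: float = 2.28                 # improvement points
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_kind not in ("spot", "bundle"):
            raise ValueError("target_kind must be 'spot' or 'bundle'")
        if self.target_kind == "spot" and self.planted_spot_center is None:
            raise ValueError("spot truth needs planted_spot_center")
        if self.target_kind == "bundle" and self.planted_bundle is None:
            raise ValueError("bundle truth needs planted_bundle")
        if self.planted_spot_center is not None:
            self.planted_spot_center = np.asarray(self.planted_spot_center, float)

    def to_dict(self) -> dict:
        return {
            "target_kind": self.target_kind,
            "planted_spot_center": None if self.planted_spot_center is None
            else self.planted_spot_center.tolist(),
            "planted_bundle": self.planted_bundle,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass
class PhantomScene:
    """Template grid, phantom nuclei and streamline bundles."""

    grid: VoxelVolume
    nucleus_center: np.ndarray            # left hemisphere, mm
    nucleus_semiaxes: np.ndarray          # mm
    bundles: dict[str, StreamlineSet]
    seed: int

    @property
    def nucleus_center_right(self) -> np.ndarray:
        return self.nucleus_center * np.array([-1.0, 1.0, 1.0])

    def nucleus_center_of(self, hemisphere: str) -> np.ndarray:
        return self.nucleus_center if hemisphere == "left" else self.nucleus_center_right

    def all_streamlines(self) -> tuple[StreamlineSet, dict[str, np.ndarray]]:
        """Concatenate bundles; returns the set plus per-group index arrays."""
        sls: list[np.ndarray] = []
        groups: dict[str, np.ndarray] = {}
        for name, sset in self.bundles.items():
            idx = np.arange(len(sls), len(sls) + len(sset))
            groups[name] = idx
            sls.extend(sset.streamlines)
        return StreamlineSet(sls), groups


def noise_sd_for_fraction(effect_size: float, fraction: float) -> float:
    """Noise SD (improvement points) making noise a given fraction of
    the total outcome SD, given a unit-SD standardized signal scaled by
    ``effect_size``."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    return effect_size * fraction / math.sqrt(1.0 - fraction**2)


def _default_grid(voxel_mm: float) -> VoxelVolume:
    # box covering both hemispheres' nuclei and peri-nucleus fields
    lo = np.array([-24.0, -20.0, -18.0])
    hi = np.array([24.0, 20.0, 22.0])
    shape = tuple(int(round(d / voxel_mm)) + 1 for d in hi - lo)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo
    return VoxelVolume(np.zeros(shape), affine, units="unitless")


def make_scene(voxel_mm: float = 1.0, seed: int = 0,
               n_per_bundle: int = 40, n_background: int = 60,
               bundle_offsets: Mapping[str, Sequence[float]] | None = None,
               min_separation_mm: float = 3.0,
               bilateral_bundles: bool = True) -> PhantomScene:
    """Build the default phantom: two ellipsoidal nuclei at x = ±10 mm
    and three streamline groups (two coherent bundles and a diffuse
    background fan) threading the peri-nucleus region.
    """
    grid = _default_grid(voxel_mm)
    nucleus_center = np.array([-10.0, -2.0, -2.0])
    nucleus_semiaxes = np.array([3.0, 5.0, 3.0])
    if bundle_offsets is None:
        bundle_offsets = {
            "target": (0.5, 3.0, 0.5),
            "decoy": (-0.5, -4.0, 0.5),
        }
    bundles = make_bundles(
        nucleus_center, bundle_offsets, seed=seed,
        n_per_bundle=n_per_bundle, n_background=n_background,
        min_separation_mm=min_separation_mm, bilateral=bilateral_bundles,
    )
    return PhantomScene(grid=grid, nucleus_center=nucleus_center,
                        nucleus_semiaxes=nucleus_semiaxes,
                        bundles=bundles, seed=seed)


def _bezier(p0, p1, p2, p3, n_points: int = 33) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t**2 * p2 + t**3 * p3)


def make_bundles(nucleus_center: np.ndarray,
                 bundle_offsets: Mapping[str, Sequence[float]],
                 seed: int = 0, n_per_bundle: int = 40,
                 n_background: int = 60, min_separation_mm: float = 3.0,
                 waypoint_jitter_mm: float = 0.8,
                 bilateral: bool = True) -> dict[str, StreamlineSet]:
    """Fans of smooth cubic curves from below the nucleus, through a
    per-bundle waypoint beside it, up to a distinct "cortical" patch.

    Bundle waypoint centers must be separated by at least
    ``min_separation_mm`` plus twice the waypoint jitter radius, so the
    realized waypoints of different bundles keep the stated minimum
    distance; an infeasible request raises.  A diffuse ``background``
    group (no waypoint constraint) is added when ``n_background > 0``.
    """
    names = list(bundle_offsets)
    centers = {n: np.asarray(nucleus_center, float) + np.asarray(bundle_offsets[n], float)
               for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            gap = np.linalg.norm(centers[a] - centers[b])
            if gap < min_separation_mm + 2 * waypoint_jitter_mm:
                raise ValueError(
                    f"bundle waypoints {a!r}/{b!r} are {gap:.2f} mm apart; "
                    f"need >= {min_separation_mm + 2 * waypoint_jitter_mm:.2f} mm "
                    f"for a {min_separation_mm} mm realized separation"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hemis = [1.0, -1.0] if bilateral else [1.0]  # sign multiplier on x... see below
    out: dict[str, StreamlineSet] = {}
    for gi, name in enumerate(names):
        sls = []
        for hs in hemis:
            mirror = np.array([1.0, 1.0, 1.0]) if hs > 0 else np.array([-1.0, 1.0, 1.0])
            w_center = centers[name] * mirror
            patch_center = (np.array([nucleus_center[0], 0.0, 20.0])
                            + np.array(bundle_offsets[name]) * np.array([2.0, 2.0, 0.0])) * mirror
            n_this = n_per_bundle // len(hemis) + (n_per_bundle % len(hemis) if hs > 0 else 0)
            for _ in range(n_this):
                # waypoint jitter confined to a ball to respect separation
                u = rng.normal(size=3)
                u = u / np.linalg.norm(u) * waypoint_jitter_mm * rng.random() ** (1 / 3)
                w = w_center + u
                start = w + np.array([0.0, 0.0, -14.0]) + rng.normal(0, 1.0, 3)
                end = patch_center + rng.normal(0, 2.5, 3)
                p1 = w + np.array([0.0, 0.0, -2.0])
                p2 = w + np.array([0.0, 0.0, 4.0])
                sls.append(_bezier(start, p1, p2, end))
        out[name] = StreamlineSet(sls)
    if n_background > 0:
        sls = []
        for hs in hemis:
            mirror = np.array([1.0, 1.0, 1.0]) if hs > 0 else np.array([-1.0, 1.0, 1.0])
            n_this = n_background // len(hemis) + (n_background % len(hemis) if hs > 0 else 0)
            for _ in range(n_this):
                w = (np.asarray(nucleus_center, float)
                     + rng.uniform([-4.0, -8.0, -4.0], [4.0, 8.0, 4.0])) * mirror
                start = w + np.array([0.0, 0.0, -14.0]) + rng.normal(0, 2.0, 3)
                end = np.array([w[0] * 1.5, w[1] * 2.0, 20.0]) + rng.normal(0, 3.0, 3)
                sls.append(_bezier(start, w + [0, 0, -2.0], w + [0, 0, 4.0], end))
        out["background"] = StreamlineSet(sls)
    return out


def simulate_efield(contacts_mm: np.ndarray, amplitude_ma: float,
                    grid: VoxelVolume, patient_id: str = "phantom",
                    hemisphere: str = "left") -> EFieldVolume:
    """Analytic inverse-square E-field magnitude from active contacts.

    magnitude(x) = sum_contacts kappa * amplitude / max(r, r0)^2 with
    kappa calibrated so a 2 mA single contact crosses 200 V/m at
    3.5 mm; r0 = 0.5 mm caps the singularity at the contact.
    """
    if amplitude_ma <= 0:
        raise ValueError("amplitude must be positive")
    contacts = np.atleast_2d(np.asarray(contacts_mm, dtype=float))
    # bounding box check in world space
    corners = grid.voxel_to_world(np.array([[0, 0, 0],
                                            [s - 1 for s in grid.shape]], float))
    lo, hi = np.minimum(*corners), np.maximum(*corners)
    for c in contacts:
        if np.any(c < lo) or np.any(c > hi):
            raise ValueError(f"contact {c.tolist()} outside grid bounds {lo.tolist()}..{hi.tolist()}")
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    mag = np.zeros(world.shape[0])
    for c in contacts:
        r = np.linalg.norm(world - c, axis=1)
        mag += FIELD_KAPPA * amplitude_ma / np.maximum(r, FIELD_CORE_RADIUS_MM) ** 2
    vol = grid.like(mag.reshape(grid.shape), units="V_per_m")
    active = contacts[0] if len(contacts) == 1 else contacts.mean(axis=0)
    return EFieldVolume(vol, patient_id=patient_id, hemisphere=hemisphere,
                        active_contact_mm=active)


def _lead_contacts(nucleus_center: np.ndarray, jitter: np.ndarray) -> np.ndarray:
    """Four contacts of a vertical linear lead; the lowest contact sits
    just below the nucleus center so the standard (second-to-lowest)
    contact lands near it."""
    tip = nucleus_center + np.array([0.0, 0.0, -CONTACT_SPACING_MM]) + jitter
    return np.array([tip + [0.0, 0.0, CONTACT_SPACING_MM * i] for i in range(4)])


def make_cohort(scene: PhantomScene, n_patients: int,
                truth: SimulationTruth,
                placement_jitter_mm: float = 1.5,
                amplitude_mean_ma: float = 2.5,
                amplitude_sd_ma: float = 0.5,
                baseline_score: float = DEFAULT_BASELINE_SCORE,
                disorder: str = "synthetic",
                write_dir: str | Path | None = None,
                ) -> tuple[Cohort, dict]:
    """Generate a bilaterally implanted phantom cohort.

    Per patient and hemisphere a four-contact lead is placed near the
    phantom nucleus with Gaussian placement jitter; the standard
    (second-to-lowest) contact is activated.  Planted-target engagement
    is the field magnitude at the planted spot (mirrored for the right
    hemisphere) or the mean peak magnitude over planted-bundle
    streamlines, averaged across hemispheres.  Improvement is
    50 + effect_size * standardized engagement + N(0, noise_sd), and
    follow-up scores are back-computed from the fixed baseline.

    Returns the cohort and a manifest dict (derived seeds, parameters);
    with ``write_dir`` the full cohort is also written to disk
    (NIfTI E-fields, TRK bundles, CSV table, manifest and truth JSON).
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    master = np.random.SeedSequence(truth.seed)
    place_ss, noise_ss = master.spawn(2)
    patient_seeds = place_ss.spawn(n_patients)
    rng_noise = np.random.default_rng(noise_ss)

    all_sls, groups = scene.all_streamlines()
    if truth.target_kind == "bundle":
        if truth.planted_bundle not in scene.bundles:
            raise ValueError(f"unknown bundle {truth.planted_bundle!r}")
        planted = scene.bundles[truth.planted_bundle]

    records: list[PatientRecord] = []
    engagements = np.empty(n_patients)
    untouched = 0
    for i in range(n_patients):
        prng = np.random.default_rng(patient_seeds[i])
        pid = f"sub-{i:03d}"
        efields = []
        eng_hemi = []
        for hemisphere in ("left", "right"):
            center = scene.nucleus_center_of(hemisphere)
            jitter = prng.normal(0.0, placement_jitter_mm, 3)
            contacts = _lead_contacts(center, jitter)
            amplitude = max(0.5, prng.normal(amplitude_mean_ma, amplitude_sd_ma))
            ef = simulate_efield(contacts[STANDARD_CONTACT][None, :], amplitude,
                                 scene.grid, patient_id=pid, hemisphere=hemisphere)
            efields.append(ef)
            if truth.target_kind == "spot":
                spot = truth.planted_spot_center
                if hemisphere == "right":
                    spot = spot * np.array([-1.0, 1.0, 1.0])
                eng_hemi.append(float(ef.volume.sample_world(spot[None, :])[0]))
            else:
                peaks = [float(np.max(ef.volume.sample_world(sl))) for sl in planted]
                eng_hemi.append(float(np.mean(peaks)))
        if max(eng_hemi) <= 0:
            untouched += 1
        engagements[i] = float(np.mean(eng_hemi))
        records.append(PatientRecord(patient_id=pid, disorder=disorder,
                                     baseline_score=baseline_score,
                                     followup_score=baseline_score,  # placeholder
                                     efields=efields))
    if untouched:
        import logging
        logging.getLogger(__name__).warning(
            "%d/%d patients have fields not touching the planted target "
            "(placement jitter too large?)", untouched, n_patients)

    sd = engagements.std()
    z = (engagements - engagements.mean()) / sd if sd > 0 else np.zeros(n_patients)
    improvements = (50.0 + truth.effect_size * z
                    + rng_noise.normal(0.0, truth.noise_sd, n_patients))
    for rec, imp in zip(records, improvements):
        rec.followup_score = baseline_score * (1.0 - imp / 100.0)

    cohort = Cohort(records=records, disorder=disorder,
                    metadata={"synthetic": True, "seed": truth.seed})
    manifest = {
        "seed": truth.seed,
        "patient_seeds": [int(s.generate_state(1)[0] % 2**31) for s in patient_seeds],
        "n_patients": n_patients,
        "placement_jitter_mm": placement_jitter_mm,
        "amplitude_mean_ma": amplitude_mean_ma,
        "amplitude_sd_ma": amplitude_sd_ma,
        "baseline_score": baseline_score,
        "engagements": engagements.tolist(),
        "truth": truth.to_dict(),
    }
    if write_dir is not None:
        _write_cohort(cohort, scene, truth, manifest, Path(write_dir))
    return cohort, manifest


def _write_cohort(cohort: Cohort, scene: PhantomScene, truth: SimulationTruth,
                  manifest: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "efields").mkdir(exist_ok=True)
    rows = []
    manifest_rows = []
    for rec in cohort:
        rows.append({"patient_id": rec.patient_id, "disorder": rec.disorder,
                     "baseline": rec.baseline_score,
                     "followup": rec.followup_score,
                     "improvement_pct": rec.improvement_pct})
        for ef in rec.efields:
            path = outdir / "efields" / f"{rec.patient_id}_{ef.hemisphere}.nii.gz"
            save_volume(ef.volume, path)
            manifest_rows.append({"patient_id": rec.patient_id,
                                  "hemisphere": ef.hemisphere,
                                  "efield_path": str(path)})
    import pandas as pd
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(outdir / "efield_manifest.csv", index=False)
    all_sls, groups = scene.all_streamlines()
    if len(all_sls):
        save_streamlines(all_sls, outdir / "bundles.trk", reference=scene.grid)
    with open(outdir / "bundle_groups.json", "w") as fh:
        json.dump({k: v.tolist() for k, v in groups.items()}, fh)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
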