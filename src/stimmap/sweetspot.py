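"""Voxel-wise sweet-spot mapping of stimulation-outcome association.

The model relates, voxel by voxel, the electric-field magnitude each
stimulation volume delivers to a location with the clinical improvement
of the stimulated patient.  Spearman rank correlation across the cohort
yields a map of positively associated voxels (the *sweet spot*) and
negatively associated ones (the *sour spot*).  The map is restricted to
voxels covered by at least a set fraction of E-fields above a magnitude
threshold, so sparsely sampled locations cannot produce spurious peaks.

The voxel-wise correlation maps are mass-univariate and descriptive;
their p-maps are not corrected for multiple testing by design.  Model
validity is instead established by cross-validated outcome estimation
(see :mod:`stimmap.stats`).

Usage follows the model/results idiom::

    mapper = SweetSpotMapper(efields, improvements)
    res = mapper.fit()
    res.r_map            # correlation VoxelVolume
    res.score(fields)    # Sweet Spot Score for one patient's fields
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import EFieldVolume, VoxelVolume, mirror_volume_x, save_volume
from .stats import spearman_map

__all__ = [
    "SweetSpotMapper",
    "SweetSpotResults",
    "coverage_mask",
    "map_sweet_spot",
    "sweet_spot_score",
]

DEFAULT_MAGNITUDE_THRESHOLD = 200.0  # V/m; common axonal activation estimate
DEFAULT_COVERAGE_FRACTION = 0.5


def _common_grid(efields: Sequence[EFieldVolume]) -> VoxelVolume:
    if not efields:
        raise ValueError("empty E-field list")
    ref = efields[0].volume
    for ef in efields[1:]:
        if not ref.same_grid(ef.volume):
            raise ValueError(
                f"E-field {ef.patient_id}/{ef.hemisphere} is not on the common grid; "
                "resample first (imaging.resample_to_grid)"
            )
    return ref


def coverage_mask(efields: Sequence[EFieldVolume],
                  magnitude_threshold: float = DEFAULT_MAGNITUDE_THRESHOLD,
                  coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
                  ) -> VoxelVolume:
    """Voxels covered by >= ``coverage_fraction`` of E-fields exceeding
    ``magnitude_threshold`` (both comparisons as stated: magnitude
    strictly above the threshold, fraction inclusive)."""
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    grid = _common_grid(efields)
    count = np.zeros(grid.shape)
    for ef in efields:
        count += ef.volume.data > magnitude_threshold
    mask = (count / len(efields)) >= coverage_fraction
    return grid.like(mask.astype(float), units="count")


@dataclass
class SweetSpotResults:
    """Fitted voxel-wise map with its provenance and scoring rule."""

    r_map: VoxelVolume
    p_map: VoxelVolume
    mask: VoxelVolume
    params: dict
    n_observations: int

    @property
    def mask_indices(self) -> np.ndarray:
        return np.argwhere(self.mask.data > 0)

    def peak_voxel_mm(self, sign: str = "positive") -> np.ndarray:
        """World coordinate of the extreme-|r| voxel inside the mask."""
        r = self.r_map.data
        m = self.mask.data > 0
        if not m.any():
            raise ValueError("empty mask")
        vals = np.where(m, r, np.nan)
        if sign == "positive":
            idx = np.unravel_index(np.nanargmax(vals), vals.shape)
        elif sign == "negative":
            idx = np.unravel_index(np.nanargmin(vals), vals.shape)
        else:  # absolute
            idx = np.unravel_index(np.nanargmax(np.abs(vals)), vals.shape)
        return self.r_map.voxel_to_world(np.asarray(idx, dtype=float))

    # -- scoring ----------------------------------------------------------
    def score_efield(self, efield: EFieldVolume) -> float:
        """Sweet Spot Score of one E-field: mean over mask voxels of
        (E-field magnitude x voxel r)."""
        if not efield.volume.same_grid(self.r_map):
            raise ValueError("E-field grid does not match the model grid")
        vol = efield.volume
        if self.params.get("mirror") and efield.hemisphere == "right":
            vol = mirror_volume_x(vol)
        m = self.mask.data > 0
        if not m.any():
            raise ValueError("empty mask")
        return float(np.mean(vol.data[m] * self.r_map.data[m]))

    def score(self, efields: Sequence[EFieldVolume]) -> float:
        """Patient-level score: hemisphere scores averaged."""
        if not efields:
            raise ValueError("patient has no E-fields")
        return float(np.mean([self.score_efield(ef) for ef in efields]))

    def score_cohort(self, cohort) -> np.ndarray:
        return np.array([self.score(rec.efields) for rec in cohort])

    def summary(self) -> str:
        m = self.mask.data > 0
        r = self.r_map.data[m]
        lines = [
            "Sweet-spot mapping results",
            f"  observations (E-fields): {self.n_observations}",
            f"  mask voxels:             {int(m.sum())}",
            f"  magnitude threshold:     {self.params['magnitude_threshold']} V/m",
            f"  coverage fraction:       {self.params['coverage_fraction']}",
            f"  r range in mask:         [{r.min():+.3f}, {r.max():+.3f}]" if m.any() else "  r range in mask:         n/a",
            f"  peak (sweet) voxel mm:   {np.round(self.peak_voxel_mm(), 2).tolist()}" if m.any() else "",
        ]
        return "\n".join(l for l in lines if l)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_volume(self.r_map, outdir / "r_map.nii.gz")
        save_volume(self.p_map, outdir / "p_map.nii.gz")
        save_volume(self.mask, outdir / "mask.nii.gz")


class SweetSpotMapper:
    """Voxel-wise stimulation-outcome mapper.

    Parameters
    ----------
    efields : sequence of EFieldVolume
        All stimulation fields pooled across patients and hemispheres,
        resampled to one common grid.  With ``mirror=True``,
        right-hemisphere fields are flipped across the template midline
        (world x = 0) onto the left, for unilateral regions of interest.
    improvements : array-like
        Percent clinical improvement of the owning patient, one entry
        per E-field (the pooled-observation convention); with
        ``aggregation="patient_max"`` fields of one patient are collapsed
        to their voxel-wise maximum and observations become patients.
    magnitude_threshold, coverage_fraction : float
        Coverage-mask parameters (defaults 200 V/m, 0.5).
    """

    def __init__(self, efields: Sequence[EFieldVolume],
                 improvements: Sequence[float],
                 magnitude_threshold: float = DEFAULT_MAGNITUDE_THRESHOLD,
                 coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
                 mirror: bool = False,
                 aggregation: str = "efield"):
        if aggregation not in ("efield", "patient_max"):
            raise ValueError("aggregation must be 'efield' or 'patient_max'")
        efields = list(efields)
        improvements = np.asarray(improvements, dtype=float)
        if len(efields) != improvements.size:
            raise ValueError("one improvement value per E-field required")
        self.grid = _common_grid(efields)
        if mirror:
            efields = [
                EFieldVolume(mirror_volume_x(ef.volume), ef.patient_id,
                             ef.hemisphere, ef.active_contact_mm)
                if ef.hemisphere == "right" else ef
                for ef in efields
            ]
        if aggregation == "patient_max":
            efields, improvements = self._collapse_patients(efields, improvements)
        if improvements.size < 4:
            raise ValueError("need at least 4 observations")
        self.efields = efields
        self.improvements = improvements
        self.magnitude_threshold = float(magnitude_threshold)
        self.coverage_fraction = float(coverage_fraction)
        self.mirror = bool(mirror)
        self.aggregation = aggregation

    @staticmethod
    def _collapse_patients(efields, improvements):
        by_patient: dict[str, list[int]] = {}
        for i, ef in enumerate(efields):
            by_patient.setdefault(ef.patient_id, []).append(i)
        out_fields, out_impr = [], []
        for pid, idxs in by_patient.items():
            vols = [efields[i].volume.data for i in idxs]
            vals = {float(improvements[i]) for i in idxs}
            if len(vals) > 1:
                raise ValueError(f"inconsistent improvements for patient {pid}")
            base = efields[idxs[0]]
            out_fields.append(EFieldVolume(
                base.volume.like(np.maximum.reduce(vols), units="V_per_m"),
                patient_id=pid, hemisphere=base.hemisphere,
                active_contact_mm=base.active_contact_mm))
            out_impr.append(vals.pop())
        return out_fields, np.asarray(out_impr)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "SweetSpotMapper":
        """Pool all E-fields of a cohort, pairing each with its
        patient's improvement."""
        efields, improvements = [], []
        for rec in cohort:
            for ef in rec.efields:
                efields.append(ef)
                improvements.append(rec.improvement_pct)
        return cls(efields, improvements, **kwargs)

    def fit(self, seed: int = 0) -> SweetSpotResults:
        """Compute the coverage mask and voxel-wise Spearman maps."""
        mask = coverage_mask(self.efields, self.magnitude_threshold,
                             self.coverage_fraction)
        m = mask.data > 0
        if not m.any():
            raise ValueError(
                f"coverage mask is empty at threshold "
                f"{self.magnitude_threshold} V/m, fraction {self.coverage_fraction}"
            )
        X = np.stack([ef.volume.data[m] for ef in self.efields])  # (n_obs, n_vox)
        rho, p = spearman_map(X, self.improvements, seed=seed)
        r_map = np.zeros(self.grid.shape)
        p_map = np.zeros(self.grid.shape)
        r_map[m] = rho
        p_map[m] = p
        params = {
            "magnitude_threshold": self.magnitude_threshold,
            "coverage_fraction": self.coverage_fraction,
            "mirror": self.mirror,
            "aggregation": self.aggregation,
        }
        return SweetSpotResults(
            r_map=self.grid.like(r_map, units="correlation"),
            p_map=self.grid.like(p_map, units="unitless"),
            mask=mask, params=params, n_observations=len(self.efields),
        )


# -- cross-validation with exact refit permutations --------------------------

def cv_permutation_test(efields_by_patient: Sequence[Sequence[EFieldVolume]],
                        improvements: Sequence[float],
                        k: int = 5, seed: int = 0,
                        n_permutations: int = 5000,
                        magnitude_threshold: float = DEFAULT_MAGNITUDE_THRESHOLD,
                        coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
                        mirror: bool = True):
    """K-fold CV of the sweet-spot model with full-refit permutations.

    Permuting outcomes only at the final correlation stage ignores the
    dependence the CV induces between held-out estimates and outcomes
    (each estimate is built from the other folds' outcomes), which
    inflates the null rejection rate.  Here every permutation re-runs
    the entire CV.  That is exact and still fast because the coverage
    mask and the voxel-wise magnitude ranks depend only on the training
    fields, never on outcomes: per fold, re-fitting under a permuted
    outcome vector reduces to one matrix product, and the Sweet Spot
    Score is linear in the voxel map.

    Returns a :class:`stimmap.stats.CVReport`.
    """
    from scipy import stats as _sps

    from .stats import CVReport, _rank, _rank_corr

    y = np.asarray(improvements, dtype=float)
    n = y.size
    if len(efields_by_patient) != n:
        raise ValueError("one E-field list per patient required")
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")

    # same fold-assignment contract as stats.kfold_cv
    ss = np.random.SeedSequence(seed)
    fold_seed, perm_seed = ss.spawn(2)
    order = np.random.default_rng(fold_seed).permutation(n)
    folds = np.array_split(order, k)
    prng = np.random.default_rng(perm_seed)
    perms = np.array([prng.permutation(n) for _ in range(n_permutations)])

    # flatten all fields once (mirrored), remember the owning patient
    fields_data: list[np.ndarray] = []
    owner: list[int] = []
    grid = None
    for i, efs in enumerate(efields_by_patient):
        if not efs:
            raise ValueError(f"patient {i} has no E-fields")
        for ef in efs:
            vol = ef.volume
            if grid is None:
                grid = vol
            elif not grid.same_grid(vol):
                raise ValueError("all E-fields must share one grid")
            if mirror and ef.hemisphere == "right":
                vol = mirror_volume_x(vol)
            fields_data.append(vol.data.ravel())
            owner.append(i)
    D = np.stack(fields_data)                       # (n_fields, n_voxels)
    owner = np.asarray(owner)

    est_obs = np.empty(n)
    est_perm = np.empty((n_permutations, n))
    fold_of_patient = np.empty(n, dtype=int)
    for f, test_idx in enumerate(folds):
        fold_of_patient[test_idx] = f
        train_pat = np.setdiff1d(np.arange(n), test_idx)
        train_rows = np.flatnonzero(np.isin(owner, train_pat))
        Xt = D[train_rows]
        count = (Xt > magnitude_threshold).sum(axis=0)
        mask = count / len(train_rows) >= coverage_fraction
        if not mask.any():
            raise RuntimeError(f"cross-validation fold {f} failed: empty coverage mask")
        cX = _sps.rankdata(Xt[:, mask], axis=0)
        cX = cX - cX.mean(axis=0)
        nrm = np.sqrt(np.einsum("ij,ij->j", cX, cX))
        nrm[nrm == 0] = np.inf
        cX /= nrm
        # per-test-patient linear map: estimate = A @ rho_vox
        A = np.stack([
            D[np.flatnonzero(owner == i)][:, mask].mean(axis=0) / mask.sum()
            for i in test_idx
        ])

        def rho_from_y(y_vec: np.ndarray) -> np.ndarray:
            ry = _sps.rankdata(y_vec[owner[train_rows]])
            cy = ry - ry.mean()
            cy /= np.sqrt(cy @ cy)
            return cy @ cX

        est_obs[test_idx] = A @ rho_from_y(y)
        ry_all = _sps.rankdata(y[perms][:, owner[train_rows]], axis=1)
        cy_all = ry_all - ry_all.mean(axis=1, keepdims=True)
        cy_all /= np.sqrt(np.einsum("ij,ij->i", cy_all, cy_all))[:, None]
        est_perm[:, test_idx] = (cy_all @ cX) @ A.T

    rho_obs = _rank_corr(_rank(est_obs), _rank(y))
    ry_perm = _sps.rankdata(y[perms], axis=1)
    re_perm = _sps.rankdata(est_perm, axis=1)
    cy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    ce = re_perm - re_perm.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", cy, ce)
    den = np.sqrt(np.einsum("ij,ij->i", cy, cy) * np.einsum("ij,ij->i", ce, ce))
    rho_null = num / den
    p_perm = float((1 + np.sum(np.abs(rho_null) >= abs(rho_obs) - 1e-12))
                   / (1 + n_permutations))
    return CVReport(fold_of_patient=fold_of_patient, estimates=est_obs,
                    rho_obs=rho_obs, p_perm=p_perm,
                    n_permutations=n_permutations, seed=seed, k=k)


# -- functional wrappers -----------------------------------------------------

def map_sweet_spot(efields: Sequence[EFieldVolume],
                   improvements: Sequence[float], **kwargs) -> SweetSpotResults:
    """Functional form of :class:`SweetSpotMapper` + ``fit``."""
    seed = kwargs.pop("seed", 0)
    return SweetSpotMapper(efields, improvements, **kwargs).fit(seed=seed)


def sweet_spot_score(efields: Sequence[EFieldVolume] | EFieldVolume,
                     results: SweetSpotResults) -> float:
    """Sweet Spot Score of a patient (or a single E-field)."""
    if isinstance(efields, EFieldVolume):
        return results.score_efield(efields)
    return results.score(list(efields))
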