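"""Streamline-level filtering of stimulation-outcome association.

Each streamline of a normative connectome is weighted by the Spearman
rank correlation between the peak E-field magnitude it is exposed to
per stimulation volume and the clinical improvement of the stimulated
patients.  Streamlines strongly modulated in good responders receive
high positive weights ("sweet" streamlines); those modulated in poor
responders receive negative weights ("sour" streamlines).

Only candidate streamlines are correlated: those traversing a high
field magnitude (> 0.8 V/mm = 800 V/m) in strictly more than 0.5% of
the cohort's E-fields.  The sweet subset is thresholded at the top 1%
of the candidate r distribution, and outcome estimation uses the
"weighted peak 5%" rule: per E-field, the largest 5% of (r x peak)
products over touched sweet streamlines are summed, then averaged
across hemispheres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import (
    DEFAULT_STEP_MM,
    EFieldVolume,
    StreamlineSet,
    resample_polyline,
    save_streamlines,
)
from .stats import spearman_map

__all__ = [
    "PeakMatrix",
    "FiberFilter",
    "FiberFilterResults",
    "select_candidates",
    "build_peak_matrix",
    "fit_fiber_model",
    "fiber_r_score",
    "specificity_ratio",
    "gaussian_contact_control",
]

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_MAGNITUDE = 800.0   # V/m  (0.8 V/mm)
DEFAULT_CANDIDATE_FRACTION = 0.005    # "more than 0.5% of E-fields", strict
DEFAULT_SWEET_TOP_FRACTION = 0.01     # top 1% of candidate r values
DEFAULT_SCORE_PEAK_FRACTION = 0.05    # weighted peak 5% scoring rule


@dataclass
class PeakMatrix:
    """Streamlines-by-E-fields matrix of peak sampled magnitudes."""

    values: np.ndarray                 # (n_streamlines, n_efields), V/m
    efield_labels: list[tuple[str, str]]  # (patient_id, hemisphere)
    streamline_index: np.ndarray       # indices into the source StreamlineSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("peak magnitudes must be non-negative")


def _resampled_points(sset: StreamlineSet, step_mm: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated dense points of all streamlines + reduceat offsets."""
    pts, offsets, total = [], [], 0
    for sl in sset:
        dense = resample_polyline(sl, step_mm)
        pts.append(dense)
        offsets.append(total)
        total += len(dense)
    return np.vstack(pts), np.asarray(offsets)


def build_peak_matrix(sset: StreamlineSet, efields: Sequence[EFieldVolume],
                      step_mm: float = DEFAULT_STEP_MM,
                      subset: np.ndarray | None = None) -> PeakMatrix:
    """Peak sampled E-field magnitude per (streamline, E-field).

    Streamlines are resampled once at ``step_mm`` arclength spacing and
    all points of one streamline are interpolated in each field in a
    single pass; the entry is the maximum over its samples (0 when the
    streamline never enters the field's support).
    """
    if subset is None:
        subset = np.arange(len(sset))
    sub = sset[np.asarray(subset)]
    if len(sub) == 0:
        return PeakMatrix(np.zeros((0, len(efields))),
                          [(e.patient_id, e.hemisphere) for e in efields],
                          np.asarray(subset))
    points, offsets = _resampled_points(sub, step_mm)
    values = np.empty((len(sub), len(efields)))
    for j, ef in enumerate(efields):
        samples = ef.volume.sample_world(points)
        values[:, j] = np.maximum.reduceat(samples, offsets)
    labels = [(e.patient_id, e.hemisphere) for e in efields]
    return PeakMatrix(values, labels, np.asarray(subset))


def select_candidates(sset: StreamlineSet, efields: Sequence[EFieldVolume],
                      candidate_magnitude: float = DEFAULT_CANDIDATE_MAGNITUDE,
                      candidate_fraction: float = DEFAULT_CANDIDATE_FRACTION,
                      step_mm: float = DEFAULT_STEP_MM,
                      peaks: PeakMatrix | None = None) -> np.ndarray:
    """Boolean flag per streamline: traverses a magnitude above
    ``candidate_magnitude`` in strictly more than ``candidate_fraction``
    of the cohort's E-fields."""
    if peaks is None:
        peaks = build_peak_matrix(sset, efields, step_mm=step_mm)
    frac = np.mean(peaks.values > candidate_magnitude, axis=1)
    return frac > candidate_fraction


@dataclass
class FiberFilterResults:
    """Per-streamline weights of a fitted fiber-filtering model.

    ``r``/``p`` are NaN outside the candidate set (those streamlines
    were never exposed to sufficient stimulation and carry no defined
    correlation).  ``certainty`` is -log10(p), the weight used to
    visualise spatial uncertainty.
    """

    r: np.ndarray
    p: np.ndarray
    candidate: np.ndarray
    sweet_threshold: float
    sweet_ids: np.ndarray
    params: dict
    n_observations: int
    streamlines: StreamlineSet | None = None
    log_base: float = 10.0
    specificity: np.ndarray | None = None

    @property
    def certainty(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return -np.log(self.p) / math.log(self.log_base)

    def sweet_set(self) -> StreamlineSet:
        if self.streamlines is None:
            raise ValueError("results carry no streamline geometry")
        return self.streamlines[self.sweet_ids]

    # -- scoring ----------------------------------------------------------
    def score_efield(self, efield: EFieldVolume,
                     peaks_row: np.ndarray | None = None) -> float:
        """Weighted peak-5% Fiber R score of one E-field.

        Among sweet streamlines with a nonzero peak under this field,
        form w = r x peak, retain the largest
        ceil(score_peak_fraction x count) values (at least one), and sum
        them.  A field touching no sweet streamline scores 0.
        """
        if self.sweet_ids.size == 0:
            raise ValueError("empty sweet streamline set; cannot score")
        if peaks_row is None:
            if self.streamlines is None:
                raise ValueError("results carry no streamline geometry")
            pm = build_peak_matrix(self.streamlines, [efield],
                                   step_mm=self.params["step_mm"],
                                   subset=self.sweet_ids)
            peaks_row = pm.values[:, 0]
        peaks_row = np.asarray(peaks_row, dtype=float)
        touched = peaks_row > 0
        if not touched.any():
            return 0.0
        w = self.r[self.sweet_ids][touched] * peaks_row[touched]
        k = max(1, math.ceil(self.params["score_peak_fraction"] * touched.sum()))
        return float(np.sort(w)[-k:].sum())

    def score(self, efields: Sequence[EFieldVolume]) -> float:
        """Patient-level score: hemisphere scores averaged."""
        if not efields:
            raise ValueError("patient has no E-fields")
        return float(np.mean([self.score_efield(ef) for ef in efields]))

    def score_cohort(self, cohort) -> np.ndarray:
        return np.array([self.score(rec.efields) for rec in cohort])

    def summary(self) -> str:
        n_cand = int(self.candidate.sum())
        lines = [
            "Fiber-filtering results",
            f"  streamlines:        {self.r.size}",
            f"  candidates:         {n_cand}",
            f"  observations:       {self.n_observations}",
            f"  sweet threshold r:  {self.sweet_threshold:+.3f}",
            f"  sweet streamlines:  {self.sweet_ids.size}",
        ]
        if n_cand:
            rc = self.r[self.candidate]
            lines.append(f"  candidate r range:  [{rc.min():+.3f}, {rc.max():+.3f}]")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        sweet = np.zeros(self.r.size, dtype=bool)
        sweet[self.sweet_ids] = True
        df = pd.DataFrame({
            "streamline_id": np.arange(self.r.size),
            "r": self.r, "p": self.p, "certainty": self.certainty,
            "candidate": self.candidate, "sweet": sweet,
        })
        if self.specificity is not None:
            df["specificity"] = self.specificity
        return df

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "fiber_model.csv", index=False)
        if self.streamlines is not None and self.sweet_ids.size:
            save_streamlines(self.sweet_set(), outdir / "sweet_streamlines.trk")


class FiberFilter:
    """Fiber-filtering model over a streamline set and a cohort's fields.

    Parameters mirror the published defaults: candidate rule 800 V/m in
    more than 0.5% of fields; sweet threshold at the top 1% of candidate
    r values; scoring with the weighted peak-5% rule.
    """

    def __init__(self, streamlines: StreamlineSet,
                 efields: Sequence[EFieldVolume],
                 improvements: Sequence[float],
                 candidate_magnitude: float = DEFAULT_CANDIDATE_MAGNITUDE,
                 candidate_fraction: float = DEFAULT_CANDIDATE_FRACTION,
                 sweet_top_fraction: float = DEFAULT_SWEET_TOP_FRACTION,
                 score_peak_fraction: float = DEFAULT_SCORE_PEAK_FRACTION,
                 step_mm: float = DEFAULT_STEP_MM):
        self.streamlines = streamlines
        self.efields = list(efields)
        self.improvements = np.asarray(improvements, dtype=float)
        if len(self.efields) != self.improvements.size:
            raise ValueError("one improvement value per E-field required")
        if self.improvements.size < 4:
            raise ValueError("need at least 4 observations")
        self.params = {
            "candidate_magnitude": float(candidate_magnitude),
            "candidate_fraction": float(candidate_fraction),
            "sweet_top_fraction": float(sweet_top_fraction),
            "score_peak_fraction": float(score_peak_fraction),
            "step_mm": float(step_mm),
        }
        self._peaks: PeakMatrix | None = None

    @classmethod
    def from_cohort(cls, streamlines: StreamlineSet, cohort, **kwargs) -> "FiberFilter":
        efields, improvements = [], []
        for rec in cohort:
            for ef in rec.efields:
                efields.append(ef)
                improvements.append(rec.improvement_pct)
        return cls(streamlines, efields, improvements, **kwargs)

    @property
    def peak_matrix(self) -> PeakMatrix:
        if self._peaks is None:
            self._peaks = build_peak_matrix(self.streamlines, self.efields,
                                            step_mm=self.params["step_mm"])
        return self._peaks

    def fit(self, seed: int = 0) -> FiberFilterResults:
        peaks = self.peak_matrix
        candidate = select_candidates(
            self.streamlines, self.efields,
            self.params["candidate_magnitude"],
            self.params["candidate_fraction"], peaks=peaks)
        n_sl = len(self.streamlines)
        r = np.full(n_sl, np.nan)
        p = np.full(n_sl, np.nan)
        if candidate.any():
            rho, pv = spearman_map(peaks.values[candidate].T,
                                   self.improvements, seed=seed)
            r[candidate] = rho
            p[candidate] = pv
            rc = r[candidate]
            # sweet threshold: top (1 - sweet_top_fraction) quantile of the
            # candidate r distribution; sweet streamlines additionally
            # require a positive association.
            sweet_threshold = float(np.quantile(rc, 1.0 - self.params["sweet_top_fraction"]))
            sweet_ids = np.where(candidate
                                 & (np.nan_to_num(r, nan=-np.inf) >= sweet_threshold)
                                 & (np.nan_to_num(r, nan=-np.inf) > 0))[0]
        else:
            sweet_threshold = float("nan")
            sweet_ids = np.array([], dtype=int)
        return FiberFilterResults(
            r=r, p=p, candidate=candidate, sweet_threshold=sweet_threshold,
            sweet_ids=sweet_ids, params=dict(self.params),
            n_observations=self.improvements.size, streamlines=self.streamlines,
        )


# -- functional wrappers -----------------------------------------------------

def fit_fiber_model(peaks: PeakMatrix, improvements: Sequence[float],
                    sweet_top_fraction: float = DEFAULT_SWEET_TOP_FRACTION,
                    score_peak_fraction: float = DEFAULT_SCORE_PEAK_FRACTION,
                    candidate: np.ndarray | None = None,
                    seed: int = 0) -> FiberFilterResults:
    """Fit per-streamline r/p from a precomputed peak matrix.

    ``candidate`` defaults to all rows (the matrix is assumed to already
    hold candidate streamlines).
    """
    improvements = np.asarray(improvements, dtype=float)
    n_sl = peaks.values.shape[0]
    if candidate is None:
        candidate = np.ones(n_sl, dtype=bool)
    r = np.full(n_sl, np.nan)
    p = np.full(n_sl, np.nan)
    if candidate.any():
        rho, pv = spearman_map(peaks.values[candidate].T, improvements, seed=seed)
        r[candidate] = rho
        p[candidate] = pv
        sweet_threshold = float(np.quantile(r[candidate], 1.0 - sweet_top_fraction))
        sweet_ids = np.where(candidate
                             & (np.nan_to_num(r, nan=-np.inf) >= sweet_threshold)
                             & (np.nan_to_num(r, nan=-np.inf) > 0))[0]
    else:
        sweet_threshold = float("nan")
        sweet_ids = np.array([], dtype=int)
    return FiberFilterResults(
        r=r, p=p, candidate=candidate, sweet_threshold=sweet_threshold,
        sweet_ids=sweet_ids,
        params={"sweet_top_fraction": sweet_top_fraction,
                "score_peak_fraction": score_peak_fraction,
                "step_mm": DEFAULT_STEP_MM},
        n_observations=improvements.size,
    )


def fiber_r_score(efields: Sequence[EFieldVolume] | EFieldVolume,
                  results: FiberFilterResults,
                  streamlines: StreamlineSet | None = None) -> float:
    """Weighted peak-5% Fiber R score for a patient or single field."""
    if streamlines is not None and results.streamlines is None:
        results.streamlines = streamlines
    if isinstance(efields, EFieldVolume):
        return results.score_efield(efields)
    return results.score(list(efields))


def specificity_ratio(results_by_disorder: Mapping[str, FiberFilterResults],
                      ) -> pd.DataFrame:
    """Per-streamline specificity: own-model r divided by the mean r the
    streamline received across the remaining disorders' models.

    Streamlines outside a model's candidate set contribute r = 0 (they
    were not exposed to that cohort's stimulation).  Where the
    cross-disorder mean is zero the ratio is undefined and NaN is
    returned, never infinity.
    """
    if len(results_by_disorder) < 2:
        raise ValueError("need at least 2 disorder models")
    names = list(results_by_disorder)
    n_sl = {d: res.r.size for d, res in results_by_disorder.items()}
    if len(set(n_sl.values())) != 1:
        raise ValueError(f"models index different streamline sets: {n_sl}")
    r_all = {d: np.nan_to_num(res.r, nan=0.0) for d, res in results_by_disorder.items()}
    out = {}
    for d in names:
        others = np.stack([r_all[o] for o in names if o != d])
        denom = others.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom != 0, r_all[d] / np.where(denom == 0, 1, denom), np.nan)
        out[d] = ratio
    return pd.DataFrame(out)


def gaussian_contact_control(contacts_by_disorder: Mapping[str, np.ndarray],
                             sset: StreamlineSet,
                             mahalanobis_cut: float = 2.0,
                             step_mm: float = DEFAULT_STEP_MM,
                             ridge_eps: float = 1e-6,
                             ) -> dict[str, np.ndarray]:
    """Placement-only control: seed streamlines from per-disorder
    Gaussians fitted to standard-contact coordinates.

    For each disorder a 3D Gaussian (mean, covariance) is fitted to the
    supplied standard (second-to-lowest) contact coordinates; a
    streamline is selected iff any sampled point lies within
    ``mahalanobis_cut`` of the Gaussian.  Singular covariances are
    ridge-regularised with a logged epsilon.

    Returns a dict disorder -> boolean selection per streamline.
    """
    points, offsets = _resampled_points(sset, step_mm) if len(sset) else (None, None)
    out: dict[str, np.ndarray] = {}
    for disorder, contacts in contacts_by_disorder.items():
        contacts = np.asarray(contacts, dtype=float)
        if contacts.ndim != 2 or contacts.shape[1] != 3 or contacts.shape[0] < 4:
            raise ValueError(f"{disorder}: need >= 4 contact coordinates (n, 3)")
        mean = contacts.mean(axis=0)
        cov = np.cov(contacts.T)
        if np.linalg.matrix_rank(cov) < 3 or np.linalg.cond(cov) > 1e12:
            logger.warning("%s: singular contact covariance, ridge eps=%g",
                           disorder, ridge_eps)
            cov = cov + ridge_eps * np.eye(3)
        prec = np.linalg.inv(cov)
        if points is None:
            out[disorder] = np.zeros(0, dtype=bool)
            continue
        d = points - mean
        md2 = np.einsum("ij,jk,ik->i", d, prec, d)
        within = md2 <= mahalanobis_cut**2
        # any sampled point within the ellipsoid selects the streamline
        sel = np.logical_or.reduceat(within, offsets) if within.size else np.zeros(len(sset), bool)
        out[disorder] = sel
    return out
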