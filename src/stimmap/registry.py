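"""Bookkeeping for the multi-center STN-DBS dataset the method targets.

These tables describe the published transdiagnostic cohorts (dystonia,
Parkinson's disease, Tourette's syndrome, obsessive-compulsive
disorder): how many bilaterally implanted patients entered each stage,
and how many electrodes received manual warp-field refinements of a
given displacement magnitude during normalization.  They are inputs to
sanity checks on electrode accounting, not computed results.
"""

from __future__ import annotations

__all__ = [
    "DISCOVERY_PATIENTS",
    "VALIDATION_PATIENTS",
    "PROSPECTIVE_CASES",
    "WARPDRIVE_DISPLACEMENT_BINS",
    "bilateral_electrode_count",
    "total_refined_electrodes",
]

#: Discovery-cohort patients per disorder (all bilaterally implanted).
DISCOVERY_PATIENTS = {"DYT": 70, "PD": 94, "OCD": 19, "TS": 14}

#: Additional retrospective validation cohorts (bilateral implants).
VALIDATION_PATIENTS = {"PD": 32, "OCD": 35}

#: Prospectively reprogrammed or implanted single cases (bilateral).
PROSPECTIVE_CASES = 3

#: Electrodes by magnitude of manual warp-field refinement applied
#: during template normalization, across the discovery cohort.
WARPDRIVE_DISPLACEMENT_BINS = {"0-1mm": 296, "1-2mm": 82, ">2mm": 16}


def bilateral_electrode_count(*patient_counts: int) -> int:
    """Electrodes implied by bilaterally implanted patient counts."""
    if any(n < 0 for n in patient_counts):
        raise ValueError("patient counts must be non-negative")
    return 2 * sum(patient_counts)


def total_refined_electrodes(bins: dict[str, int] | None = None) -> int:
    """Total electrodes across displacement-refinement bins."""
    b = WARPDRIVE_DISPLACEMENT_BINS if bins is None else bins
    if any(v < 0 for v in b.values()):
        raise ValueError("bin counts must be non-negative")
    return sum(b.values())
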