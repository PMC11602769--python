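"""Clinician-rated symptom scales tracked by the pipeline.

Four instrument totals are modelled jointly: BPRS (psychotic/general
symptoms), HAM-A (anxiety), MADRS (depression) and YMRS (mania). Score
ranges are configurable; the defaults below are the full theoretical
ranges of the common instrument versions and are used to normalize
severities, clip simulated scores, and compute NRMSE denominators.
"""

from __future__ import annotations

SCALE_NAMES: tuple[str, ...] = ("BPRS", "HAMA", "MADRS", "YMRS")

#: scale -> (min total, max total)
DEFAULT_SCALE_RANGES: dict[str, tuple[int, int]] = {
    "BPRS": (0, 108),
    "HAMA": (0, 56),
    "MADRS": (0, 60),
    "YMRS": (0, 60),
}


def scale_span(scale: str, ranges: dict[str, tuple[int, int]] | None = None) -> float:
    """Width of a scale's score range (NRMSE denominator)."""
    lo, hi = (ranges or DEFAULT_SCALE_RANGES)[scale]
    return float(hi - lo)
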