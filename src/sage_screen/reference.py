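"""Published reference values from the instrument's initial test-retest
validation study (nonclinical sample, n = 42 retested within 7 days).

These are inputs for worked examples and for checking the interpretation
banding — they are never produced by this package's computations.
"""

from __future__ import annotations

from .psychometrics import band

#: Printed test-retest coefficients per diagnostic screening module.
#: Multi-coefficient modules list every printed value (the four
#: trauma-exposure kappas; the psychotic module and its hallucination and
#: delusion sub-scores). ``None`` marks the module whose coefficient could
#: not be calculated (a single stable endorser of other-substance use).
PUBLISHED_RETEST_COEFFICIENTS: dict[str, list[float] | None] = {
    "dep": [0.67],
    "mania": [0.50],
    "gad": [0.60],
    "panic": [0.86],
    "agora": [0.90],
    "social": [0.83],
    "ocd": [0.68],
    "ptsd": [0.86, 0.60, 0.76, 0.79],
    "adhd": [0.63],
    "psych": [0.72, 0.65, 0.74],
    "alcohol": [0.70],
    "cannabis": [0.84],
    "othersub": None,
}


def published_module_bands(cut_high: float = 0.75) -> dict[str, str]:
    """Interpretation band per module, aggregating multi-coefficient modules
    by their minimum printed value; the unanalyzable module maps to
    ``not_analyzable``."""
    out = {}
    for module_id, values in PUBLISHED_RETEST_COEFFICIENTS.items():
        if values is None:
            out[module_id] = "not_analyzable"
        else:
            out[module_id] = band(min(values), cut_high=cut_high)
    return out


def count_good_or_better(cut_high: float = 0.75) -> int:
    """Number of the 13 screening modules whose aggregate band is good or
    excellent under the published coefficients."""
    return sum(
        1 for b in published_module_bands(cut_high).values()
        if b in ("good", "excellent")
    )
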