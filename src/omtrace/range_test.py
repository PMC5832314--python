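"""Mass-conservation (bracket) screening of candidate tracers.

A tracer can only behave conservatively in a linear mixture if the sediment
values lie inside the envelope spanned by the source samples.  Each tracer is
tested per subcatchment: it passes when the closed interval
[min, max] of the sediment samples is contained in the closed interval
spanned by all source samples of all categories (boundary equality counts as
a pass).  Only passing tracers are forwarded to signature selection.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data_model import SEDIMENT, SOURCE, SampleRecord, TracerPanel, ValidationError


@dataclass(frozen=True)
class RangeTestReport:
    """Per-tracer bracket-test outcome."""

    tracers: tuple
    passed: Mapping[str, bool]
    sediment_range: Mapping[str, tuple]
    source_envelope: Mapping[str, tuple]

    def passing(self) -> tuple:
        """Tracers that passed, in panel order."""
        return tuple(t for t in self.tracers if self.passed[t])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tracer": list(self.tracers),
                "pass": [self.passed[t] for t in self.tracers],
                "sediment_min": [self.sediment_range[t][0] for t in self.tracers],
                "sediment_max": [self.sediment_range[t][1] for t in self.tracers],
                "source_min": [self.source_envelope[t][0] for t in self.tracers],
                "source_max": [self.source_envelope[t][1] for t in self.tracers],
            }
        )


def bracket_test(
    sources: Sequence[SampleRecord],
    sediments: Sequence[SampleRecord],
    panel: TracerPanel,
) -> RangeTestReport:
    """Apply the mass-conservation bracket test to every panel tracer.

    Requires source samples from at least two categories and at least one
    sediment sample; every record must carry every panel tracer.  The source
    envelope is the pooled axis-aligned range over all source samples of all
    categories.
    """
    if not sediments:
        raise ValidationError("bracket test needs at least one sediment sample")
    categories = {r.category for r in sources if r.role == SOURCE}
    if len(categories) < 2:
        raise ValidationError("bracket test needs sources from >= 2 categories")
    if any(r.role != SOURCE for r in sources):
        raise ValidationError("non-source record passed as source")
    if any(r.role != SEDIMENT for r in sediments):
        raise ValidationError("non-sediment record passed as sediment")

    passed, sed_range, env = {}, {}, {}
    for t in panel.names:
        try:
            src_vals = [r.values[t] for r in sources]
            sed_vals = [r.values[t] for r in sediments]
        except KeyError:
            raise ValidationError(f"tracer {t!r} absent from a record") from None
        lo, hi = min(src_vals), max(src_vals)
        slo, shi = min(sed_vals), max(sed_vals)
        env[t] = (lo, hi)
        sed_range[t] = (slo, shi)
        passed[t] = (slo >= lo) and (shi <= hi)
    return RangeTestReport(
        tracers=tuple(panel.names),
        passed=passed,
        sediment_range=sed_range,
        source_envelope=env,
    )
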