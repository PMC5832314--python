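import numpy as np
import pytest

import omtrace as ot
from omtrace.data_model import summarize_group


@pytest.fixture(scope="session")
def panel():
    return ot.default_panel()


@pytest.fixture(scope="session")
def source_model(panel):
    return ot.default_source_model(panel, separation=1.2, cv=0.08, n_samples=8, seed=11)


@pytest.fixture(scope="session")
def sources(source_model):
    return ot.generate_sources(source_model, seed=101)


@pytest.fixture(scope="session")
def design():
    return ot.MixtureDesign(
        true_p=dict(zip(ot.DEFAULT_CATEGORIES, [0.5, 0.3, 0.15, 0.05])),
        sediment_noise_cv=0.02,
    )


@pytest.fixture(scope="session")
def sediments(source_model, design):
    return ot.generate_sediment(source_model, design, seed=202)


@pytest.fixture(scope="session")
def source_summaries(sources):
    by_cat = {}
    for r in sources:
        by_cat.setdefault(r.category, []).append(r)
    return [summarize_group(grp) for grp in by_cat.values()]


@pytest.fixture(scope="session")
def sediment_summary(sediments):
    return summarize_group(sediments)


def make_records(values_by_sample, role="source", category="farmyard_manure",
                 subcatchment="sub"):
    """Helper: build SampleRecords from {sample_id: {tracer: value}}."""
    records = []
    for sample_id, values in values_by_sample.items():
        records.append(
            ot.SampleRecord(
                sample_id=sample_id,
                role=role,
                category=category if role == "source" else None,
                subcatchment=subcatchment,
                values=values,
            )
        )
    return records
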