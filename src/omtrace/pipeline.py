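"""End-to-end orchestration: screen -> select -> unmix -> summarise, and SOD.

All randomness flows from a single root seed, split deterministically per
subcatchment and signature, so a rerun with the same configuration is
byte-identical.  Every output CSV starts with comment lines recording the
seed and a hash of the configuration.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import signature_selection, sod, uncertainty, unmixing
from .data_model import (
    SEDIMENT,
    SOURCE,
    SampleRecord,
    TracerPanel,
    ValidationError,
    average_replicates,
    read_oxygen_table,
    read_tracer_table,
    summarize_group,
)
from .range_test import bracket_test
from .signature_selection import CompositeSignature
from .synthetic_data import default_panel
from .uncertainty import MonteCarloConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remedy hint."""

    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} (hint: {hint})")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full apportionment / SOD run."""

    tracer_table: str | None = None
    oxygen_table: str | None = None
    out_dir: str = "omtrace_out"
    seed: int = 0
    # Monte Carlo block
    n_accept: int = 5000
    gof_threshold: float = 0.85
    n_bins: int = 100
    max_draws: int | None = None
    perturb_sediment: bool = True
    literal_eq3: bool = False
    solver_starts: str = "full"
    # GA block
    ga_n_repeats: int = 200
    ga_population: int = 50
    ga_generations: int = 40
    ga_p_entry: float = 0.05
    # other selection settings
    kw_alpha: float = 0.05
    min_signature_size: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        for key in ("tracer_table", "oxygen_table", "out_dir"):  # environment, not analysis
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _mc_seed(root_seed: int, subcatchment: str, signature_index: int) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(
        f"{root_seed}:{subcatchment}:{signature_index}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed}\n# config={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def select_signatures(
    sources: Sequence[SampleRecord],
    candidate_tracers: Sequence[str],
    config: PipelineConfig,
    seed: int,
) -> list:
    """The five composite signatures: three GA-DFA plus KW-H plus PCA.
    A selection route that fails on this data set is skipped with a log
    message; at least one signature must survive."""
    signatures: list = []
    try:
        signatures.extend(
            signature_selection.select_ga_dfa(
                sources,
                candidate_tracers,
                n_repeats=config.ga_n_repeats,
                p_entry=config.ga_p_entry,
                seed=seed,
                population=config.ga_population,
                generations=config.ga_generations,
            )
        )
    except ValidationError as e:
        logger.warning("GA-DFA selection skipped: %s", e)
    for fn, kwargs in (
        (signature_selection.select_kw_h, {"alpha": config.kw_alpha, "min_size": config.min_signature_size}),
        (signature_selection.select_pca, {"min_size": config.min_signature_size}),
    ):
        try:
            signatures.append(fn(sources, candidate_tracers, **kwargs))
        except ValidationError as e:
            logger.warning("%s selection skipped: %s", fn.__name__, e)
    if not signatures:
        raise ValidationError("every selection route failed")
    return signatures


def run_apportionment(
    config: PipelineConfig,
    panel: TracerPanel | None = None,
    records: Sequence[SampleRecord] | None = None,
    signature: CompositeSignature | None = None,
) -> dict:
    """Execute the apportionment pipeline and write per-stage CSVs.

    ``records`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.tracer_table`` is read.  When ``signature`` is given,
    selection is skipped and the Monte Carlo runs on that signature alone.
    Returns ``{subcatchment: {"signatures": [...], "mc": [...],
    "combined": {...}}, "catchment": {...}}``.
    """
    panel = panel or default_panel()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if records is None:
        if config.tracer_table is None:
            raise StageError("read", "provide tracer_table or records", ValueError("no input"))
        try:
            records = read_tracer_table(config.tracer_table, panel)
        except Exception as e:
            raise StageError("read", "check tracer table schema", e) from e
    records = average_replicates(records)

    subcatchments = sorted({r.subcatchment for r in records})
    results: dict = {}
    combined_by_sub: dict = {}
    rows_apportion = []
    for sub in subcatchments:
        sub_records = [r for r in records if r.subcatchment == sub]
        sources = [r for r in sub_records if r.role == SOURCE]
        sediments = [r for r in sub_records if r.role == SEDIMENT]
        try:
            report = bracket_test(sources, sediments, panel)
        except ValidationError as e:
            raise StageError("range_test", "check source/sediment coverage", e) from e
        _write_csv(report.to_frame(), out_dir / f"bracket_{sub}.csv", config)
        passing = report.passing()
        if not passing:
            raise StageError(
                "range_test",
                "no tracer passed the bracket test; check the tracer panel",
                ValidationError(f"subcatchment {sub}: empty pass set"),
            )

        if signature is not None:
            signatures = [signature]
        else:
            try:
                signatures = select_signatures(
                    sources, passing, config, _mc_seed(config.seed, sub, -1)
                )
            except ValidationError as e:
                raise StageError("selection", "relax selection settings", e) from e
        sig_rows = []
        for s in signatures:
            for t in s.tracers:
                sig_rows.append(
                    {
                        "method": s.method,
                        "tracer": t,
                        "classification_pct": s.classification_pct[t],
                        "tdw": s.tdw[t],
                        "overall_pct": s.overall_classification_pct,
                    }
                )
        _write_csv(pd.DataFrame(sig_rows), out_dir / f"signatures_{sub}.csv", config)

        by_cat = {}
        for r in sources:
            by_cat.setdefault(r.category, []).append(r)
        source_summaries = [summarize_group(grp) for grp in by_cat.values()]
        sediment_summary = summarize_group(sediments)

        mc_results = []
        sig_outcomes = []
        for k, s in enumerate(signatures):
            cfg = MonteCarloConfig(
                n_accept=config.n_accept,
                gof_threshold=config.gof_threshold,
                n_bins=config.n_bins,
                max_draws=config.max_draws,
                seed=_mc_seed(config.seed, sub, k),
            )
            try:
                mc = uncertainty.run_monte_carlo(
                    s,
                    source_summaries,
                    sediment_summary,
                    cfg,
                    literal=config.literal_eq3,
                    perturb_sediment=config.perturb_sediment,
                    solver_starts=config.solver_starts,
                )
            except uncertainty.MonteCarloError as e:
                raise StageError(
                    "monte_carlo", "lower --gof-threshold or raise max_draws", e
                ) from e
            mc_results.append(mc)
            r_map = {
                cat: mc.posteriors[cat].r_weighted_mean for cat in mc.categories
            }
            sig_outcomes.append((r_map, mc.mean_gof, s.overall_classification_pct))
            for cat in mc.categories:
                rows_apportion.append(
                    {
                        "subcatchment": sub,
                        "signature": f"{s.method}#{k + 1}",
                        "category": cat,
                        "R": round(r_map[cat], 4),
                        "mean_gof": round(mc.mean_gof, 4),
                        "overall_pct": s.overall_classification_pct,
                    }
                )
            hist_rows = []
            for cat in mc.categories:
                dist = mc.posteriors[cat]
                for v, f in zip(dist.bin_mid, dist.frequency):
                    hist_rows.append(
                        {"category": cat, "bin_mid": v, "frequency": f}
                    )
            _write_csv(
                pd.DataFrame(hist_rows),
                out_dir / f"posteriors_{sub}_{k + 1}_{s.method.replace('/', '-')}.csv",
                config,
            )

        combined = uncertainty.combine_signatures(sig_outcomes)
        combined_by_sub[sub] = combined
        for cat, v in combined.items():
            rows_apportion.append(
                {
                    "subcatchment": sub,
                    "signature": "combined",
                    "category": cat,
                    "R": v,
                    "mean_gof": "",
                    "overall_pct": "",
                }
            )
        results[sub] = {
            "signatures": signatures,
            "mc": mc_results,
            "combined": combined,
        }

    _write_csv(pd.DataFrame(rows_apportion), out_dir / "apportionment.csv", config)
    catchment = uncertainty.catchment_summary(combined_by_sub)
    _write_csv(
        pd.DataFrame(
            [{"category": cat, "mean_pct": v} for cat, v in catchment.items()]
        ),
        out_dir / "catchment_summary.csv",
        config,
    )
    results["catchment"] = catchment
    return results


def run_sod(config: PipelineConfig, series=None) -> pd.DataFrame:
    """Per-flask SOD results plus site-aggregated means, written as CSVs.

    The site of a flask is the part of its id before the final ``-``.
    Blank series (averaged onto the first blank's grid when several exist)
    correct every sample flask.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if series is None:
        if config.oxygen_table is None:
            raise StageError("read", "provide oxygen_table or series", ValueError("no input"))
        series = read_oxygen_table(config.oxygen_table)
    samples = [s for s in series if not s.is_blank]
    blanks = [s for s in series if s.is_blank]
    if not samples:
        raise StageError(
            "sod", "oxygen table holds blanks only", ValidationError("no sample flasks")
        )
    blank = None
    if blanks:
        blank = blanks[0]
        if len(blanks) > 1:
            # average blanks on the first blank's grid
            base_mid, base_rates = sod.soc_rate(blanks[0])
            acc = np.zeros_like(base_rates)
            for b in blanks:
                mid, rates = sod.soc_rate(b)
                acc += np.interp(base_mid, mid, rates)
            acc /= len(blanks)
            # rebuild a synthetic averaged blank mass series consistent with the rates
            blank = blanks[0]
            blank_rates = (base_mid, acc)
        else:
            blank_rates = sod.soc_rate(blank)
    rows = []
    for s in samples:
        mid, rates = sod.soc_rate(s)
        if blanks:
            rates = sod.blank_correct(mid, rates, *blank_rates)
        else:
            logger.warning("no blank series: rates used uncorrected")
        rates20 = sod.q10_normalize(rates, s.temperature_c)
        soc5 = sod.integrate_soc(mid, rates20, (0.0, 5.0))
        soc20 = sod.integrate_soc(mid, rates20, (0.0, 20.0))
        sod5, sod20 = sod.sod_values(soc5, soc20, s.dry_mass_g)
        site = s.flask_id.rsplit("-", 1)[0] if "-" in s.flask_id else s.flask_id
        rows.append(
            {
                "flask_id": s.flask_id,
                "site": site,
                "soc5_mg": round(soc5, 6),
                "soc20_mg": round(soc20, 6),
                "sod5_mg_per_g": round(sod5, 6),
                "sod20_mg_per_g": round(sod20, 6),
            }
        )
    per_flask = pd.DataFrame(rows)
    _write_csv(per_flask, out_dir / "sod_per_flask.csv", config)
    by_site = (
        per_flask.groupby("site")
        .agg(
            sod5_mg_per_g=("sod5_mg_per_g", "mean"),
            sod20_mg_per_g=("sod20_mg_per_g", "mean"),
            n_flasks=("flask_id", "count"),
        )
        .reset_index()
    )
    _write_csv(by_site, out_dir / "sod_by_site.csv", config)
    return per_flask
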