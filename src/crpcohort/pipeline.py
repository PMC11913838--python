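"""One-shot reproducible run: simulate (or read) -> cohort -> eligibility ->
CKD classification -> prevalence -> characterization, with a checksum
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .characterize import (baseline_table, comorbidity_history,
                           drug_utilization, extract_baseline,
                           render_baseline_text, utilization_table)
from .cohort import build_cohort
from .config import RunConfig, dump_config
from .model import EventStore, read_event_tables, write_event_tables
from .prevalence import (estimates_table, period_prevalence,
                         point_prevalence_at_cutoff, prevalence_at_first_crp,
                         sensitivity_exclude_inflammatory)
from .simulate import generate

log = logging.getLogger("crpcohort")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif out[col].dtype == object and len(out) and \
                isinstance(out[col].iloc[0], tuple):
            out[col] = out[col].map(
                lambda t: ";".join(str(x) for x in t))
    out.to_csv(path, index=False)


def run_all(config: RunConfig, outdir: str | Path,
            store: EventStore | None = None) -> dict:
    """Run every stage and write all outputs under *outdir*.

    With no *store*, synthetic tables are generated from ``config.generator``
    and written alongside the results.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if store is None:
        log.info("simulating %d patients (seed %d)",
                 config.generator.n_patients, config.generator.seed)
        store, truth = generate(config)
        tdir = outdir / "tables"
        written += list(write_event_tables(store, tdir).values())
        truth_path = tdir / "ground_truth.csv"
        _write_df(truth.patients, truth_path)
        written.append(truth_path)

    records, grouped, exclusion_log, flow = build_cohort(store, config)
    log.info("flowchart: %s", flow.as_dict())

    _write_df(records, outdir / "index_records.csv")
    _write_df(grouped, outdir / "eligible_crp.csv")
    _write_df(exclusion_log, outdir / "exclusion_log.csv")
    written += [outdir / "index_records.csv", outdir / "eligible_crp.csv",
                outdir / "exclusion_log.csv"]

    flow_path = outdir / "flowchart.json"
    flow_path.write_text(json.dumps(flow.as_dict(), indent=2) + "\n")
    written.append(flow_path)

    estimates = (prevalence_at_first_crp(records)
                 + point_prevalence_at_cutoff(records, grouped,
                                              store.patients, config)
                 + period_prevalence(records, grouped, config))
    _write_df(estimates_table(estimates), outdir / "prevalence.csv")
    written.append(outdir / "prevalence.csv")

    if config.switches.sensitivity_analysis:
        lists = config.resolved_code_lists()
        sens = sensitivity_exclude_inflammatory(
            records, grouped, store.patients, store.diagnoses,
            lists["inflammatory_rheumatoid"], config)
        sens_df = pd.concat([estimates_table(v) for v in sens.values()],
                            ignore_index=True)
        _write_df(sens_df, outdir / "prevalence_sensitivity.csv")
        written.append(outdir / "prevalence_sensitivity.csv")

    lists = config.resolved_code_lists()
    baseline = extract_baseline(records, store, config)
    comorb = comorbidity_history(records, store.diagnoses, lists, config)
    table1 = baseline_table(baseline, comorb, records)
    _write_df(table1, outdir / "baseline_table.csv")
    (outdir / "baseline_table.txt").write_text(render_baseline_text(table1) + "\n")
    written += [outdir / "baseline_table.csv", outdir / "baseline_table.txt"]

    for window in ("pre", "post"):
        util = drug_utilization(records, store.prescriptions, lists, window,
                                config)
        _write_df(utilization_table(util, records, window),
                  outdir / f"utilization_{window}.csv")
        written.append(outdir / f"utilization_{window}.csv")

    config_path = outdir / "config.yaml"
    dump_config(config, config_path)
    written.append(config_path)

    manifest = {
        "crpcohort_version": __version__,
        "seed": config.generator.seed,
        "flowchart": flow.as_dict(),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_store(indir: str | Path) -> EventStore:
    """Read the five event tables from a directory written by ``simulate``."""
    indir = Path(indir)
    paths = {name: indir / f"{name}.csv"
             for name in ("patients", "diagnoses", "prescriptions", "labs",
                          "vitals")}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input tables: {missing}")
    store, report = read_event_tables(paths)
    if report.total_rejected:
        log.warning("rejected %d rows: %s", report.total_rejected,
                    dict(report.reasons))
    return store
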