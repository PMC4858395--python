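"""End-to-end curation pipeline and report writers.

``run_pipeline`` executes the full funnel — read records, score the six
minimum criteria, keep guideline-like (GL) studies, drop mixture
exclusions, tabulate outcomes by design, and summarize per-chemical
concordance — and writes plain-CSV reports with stable column order plus
a JSON run manifest echoing the configuration, input checksums and the
record count at every stage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import concordance as cc
from . import io as uio
from . import rules


@dataclass
class PipelineConfig:
    inputs: list[str]
    out_dir: str
    control_casrns: set[str] = field(
        default_factory=lambda: set(cc.DEFAULT_CONTROL_CASRNS))
    mixture_casrns: set[str] = field(
        default_factory=lambda: set(cc.DEFAULT_MIXTURE_CASRNS))
    strict: bool = False


def score_frame(records: Sequence) -> pd.DataFrame:
    """Per-study criterion scores: record_id, mc1..mc6, total, is_gl, reasons."""
    rows = []
    for r in records:
        s = rules.score_study(r)
        row = {"record_id": s.record_id}
        for res in s.results:
            row[res.criterion_id.lower()] = res.score
        row["total"] = s.total
        row["is_gl"] = s.is_gl
        row["reasons"] = ";".join(res.reason for res in s.results if res.score == 0)
        rows.append(row)
    cols = ["record_id", "mc1", "mc2", "mc3", "mc4", "mc5", "mc6",
            "total", "is_gl", "reasons"]
    return pd.DataFrame(rows, columns=cols)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full funnel and write reports; returns the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    records = []
    for path in config.inputs:
        records.extend(uio.read_records(path, strict=config.strict))

    scores = score_frame(records)
    scores.to_csv(os.path.join(config.out_dir, "study_scores.csv"), index=False)

    gl = rules.filter_gl(records)
    analyzed = cc.apply_exclusions(gl, config.mixture_casrns)

    summary = cc.summarize_by_design(analyzed, config.control_casrns)
    summary.table.to_csv(os.path.join(config.out_dir, "design_summary.csv"))

    chems = cc.summarize_chemicals(analyzed)
    cc.chemical_summary_frame(chems).to_csv(
        os.path.join(config.out_dir, "chemical_summary.csv"), index=False)

    manifest = {
        "inputs": [{"path": p, "sha256": _sha256(p)} for p in config.inputs],
        "config": {
            "control_casrns": sorted(config.control_casrns),
            "mixture_casrns": sorted(config.mixture_casrns),
            "strict": config.strict,
        },
        "counts": {
            "records_read": len(records),
            "gl_records": len(gl),
            "after_mixture_exclusion": len(analyzed),
            "excluded_positive_control": summary.excluded_control_count,
            "chemicals": len(chems),
        },
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
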