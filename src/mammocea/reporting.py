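"""Tabular outputs and run manifests.

Money is rounded to 2 d.p. and QALYs to 1 d.p. in CSV tables; a
companion JSON carries full precision.  Every CSV embeds the manifest
(config hash, seed, schema version, scenario labels) as ``#`` header
lines; the wall-clock timestamp lives only in ``manifest.json`` so that
reruns with the same configuration and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .economics import EconomicResult, IncrementalComparison
from .natural_history import CohortTrace
from .parameters import ParameterBundle, bundle_to_dict
from .uncertainty import PsaResult, TornadoTable


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    schema_version: int
    timestamp: str
    scenarios: list[str]

    def header_lines(self) -> list[str]:
        """Deterministic header lines embedded in every CSV (no timestamp)."""
        return [
            f"# config_hash: {self.config_hash}",
            f"# seed: {self.seed}",
            f"# schema_version: {self.schema_version}",
            f"# scenarios: {','.join(self.scenarios)}",
        ]


def config_hash(bundle: ParameterBundle) -> str:
    """SHA-256 of the canonical YAML serialisation of the bundle."""
    doc = yaml.safe_dump(bundle_to_dict(bundle), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def make_manifest(
    bundle: ParameterBundle, seed: int, scenarios: list[str]
) -> RunManifest:
    return RunManifest(
        config_hash=config_hash(bundle),
        seed=seed,
        schema_version=bundle.schema_version,
        timestamp=datetime.now(timezone.utc).isoformat(),
        scenarios=scenarios,
    )


#: metric rows of the outcomes table, in display order
OUTCOME_METRICS = (
    "Total mammograms",
    "True positives",
    "True negatives",
    "False positives",
    "False negatives",
    "Undiagnosed cancer cases",
    "Early-stage detections",
    "Late-stage detections",
    "Total cost (SGD)",
    "Total QALYs",
    "ICER vs reference (SGD/QALY)",
)


def outcomes_table(
    evals: dict[str, tuple[CohortTrace, EconomicResult]],
    comparisons: dict[str, IncrementalComparison],
    reference: str = "conventional",
) -> pd.DataFrame:
    """Cumulative diagnostic outcomes, costs, health effects and the
    incremental block, one column per strategy."""
    cols = {}
    for name, (trace, econ) in evals.items():
        t = trace.tallies()
        cmp = comparisons.get(name)
        cols[name] = {
            "Total mammograms": round(t["mammograms"], 1),
            "True positives": round(t["tp"], 1),
            "True negatives": round(t["tn"], 1),
            "False positives": round(t["fp"], 1),
            "False negatives": round(t["fn"], 1),
            "Undiagnosed cancer cases": round(t["undiagnosed_cases"], 1),
            "Early-stage detections": round(t["early_stage"], 1),
            "Late-stage detections": round(t["late_stage"], 1),
            "Total cost (SGD)": round(econ.total_cost, 2),
            "Total QALYs": round(econ.total_qalys, 1),
            "ICER vs reference (SGD/QALY)": (
                ""
                if name == reference
                else (round(cmp.icer, 2) if cmp is not None and cmp.icer is not None else cmp.label if cmp else "")
            ),
            "Incremental cost (SGD)": (
                "" if name == reference else round(cmp.delta_cost, 2)
            ),
            "Incremental QALYs": (
                "" if name == reference else round(cmp.delta_qalys, 1)
            ),
            "NMB at WTP (SGD)": ("" if name == reference else round(cmp.nmb, 2)),
        }
    frame = pd.DataFrame(cols)
    frame.index.name = "metric"
    return frame


def results_json(
    evals: dict[str, tuple[CohortTrace, EconomicResult]],
    comparisons: dict[str, IncrementalComparison],
) -> dict:
    """Full-precision machine-readable companion to the outcomes table."""
    out: dict = {}
    for name, (trace, econ) in evals.items():
        entry = {
            "tallies": trace.tallies(),
            "total_cost": econ.total_cost,
            "total_qalys": econ.total_qalys,
            "cost_breakdown": econ.breakdown,
        }
        if name in comparisons:
            cmp = comparisons[name]
            entry["incremental"] = {
                "delta_cost": cmp.delta_cost,
                "delta_qalys": cmp.delta_qalys,
                "icer": cmp.icer,
                "nmb": cmp.nmb,
                "label": cmp.label,
            }
        out[name] = entry
    return out


def ceac_table(psa: PsaResult) -> pd.DataFrame:
    """Long-format CEAC: scenario, strategy, wtp, probability."""
    rows = []
    for surf in psa.surfaces:
        stacked = surf.probability.stack()
        for (wtp, strategy), p in stacked.items():
            rows.append(
                {
                    "scenario": surf.scenario,
                    "strategy": strategy,
                    "wtp": wtp,
                    "probability": p,
                }
            )
    return pd.DataFrame(rows)


def tornado_table(tt: TornadoTable) -> pd.DataFrame:
    frame = tt.table.copy()
    frame.insert(0, "comparison", f"{tt.candidate} vs {tt.reference}")
    return frame


def write_csv(frame: pd.DataFrame, path: Path, manifest: RunManifest, index: bool) -> None:
    body = frame.to_csv(index=index)
    path.write_text("\n".join(manifest.header_lines()) + "\n" + body)


def write_manifest(manifest: RunManifest, path: Path) -> None:
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
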