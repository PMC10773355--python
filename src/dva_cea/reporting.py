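"""Publication-style outputs: the base-case results table, figures, manifests.

All internal arithmetic is unrounded; display rounding (whole pounds,
three-decimal QALYs) happens only at formatting time, and the data files
always hold the unrounded values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .economics import ScenarioResult, run_scenario
from .errors import DvaCeaError
from .markov import write_trace
from .parameters import ParameterSet


@dataclass
class BaseCaseReport:
    """Deterministic base-case results for both arms plus the comparison."""

    scenario: ScenarioResult
    wtp_lambda: float

    def to_frame(self) -> pd.DataFrame:
        """Unrounded results, one row per arm plus the difference row."""
        inc = self.scenario.incremental
        return pd.DataFrame(
            [
                {
                    "row": "intervention",
                    "cost": self.scenario.intervention.total_discounted_cost,
                    "qalys": self.scenario.intervention.total_discounted_qalys,
                },
                {
                    "row": "control",
                    "cost": self.scenario.control.total_discounted_cost,
                    "qalys": self.scenario.control.total_discounted_qalys,
                },
                {
                    "row": "difference",
                    "cost": inc.delta_cost,
                    "qalys": inc.delta_qalys,
                },
            ]
        )

    def format_table(self) -> str:
        """Human-readable table: whole pounds, 3-decimal QALYs."""
        inc = self.scenario.incremental
        lines = [
            f"{'':<28}{'Costs':>10}{'QALYs':>10}",
            f"{'Intervention (IRIS+)':<28}"
            f"{'£%.0f' % self.scenario.intervention.total_discounted_cost:>10}"
            f"{self.scenario.intervention.total_discounted_qalys:>10.3f}",
            f"{'Control (IRIS, usual care)':<28}"
            f"{'£%.0f' % self.scenario.control.total_discounted_cost:>10}"
            f"{self.scenario.control.total_discounted_qalys:>10.3f}",
            f"{'Difference':<28}"
            f"{'£%.0f' % inc.delta_cost:>10}{inc.delta_qalys:>10.3f}",
            f"Verdict: {inc.verdict}"
            + (f" (ICER £{inc.icer:.0f}/QALY)" if inc.icer is not None else ""),
            f"Incremental NMB at £{self.wtp_lambda:.0f}/QALY: £{inc.nmb:.0f}",
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> list[Path]:
        """Write per-arm traces, per-cycle streams and the summary JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for arm, trace in (
            ("intervention", self.scenario.trace_intervention),
            ("control", self.scenario.trace_control),
        ):
            p = outdir / f"trace_{arm}.csv"
            write_trace(trace, p, arm)
            paths.append(p)
        streams = []
        for arm, res in (
            ("intervention", self.scenario.intervention),
            ("control", self.scenario.control),
        ):
            n = res.cost_stream.size
            frame = pd.DataFrame(
                {
                    "arm": arm,
                    "cycle": np.arange(1, n + 1),
                    "cost": res.cost_stream,
                    "qalys": res.qaly_stream,
                }
            )
            for name, comp in res.cost_components.items():
                frame[f"cost_{name}"] = comp
            streams.append(frame)
        streams_path = outdir / "streams.csv"
        pd.concat(streams, ignore_index=True).to_csv(streams_path, index=False)
        paths.append(streams_path)
        inc = self.scenario.incremental
        summary_path = outdir / "base_case.json"
        summary_path.write_text(
            json.dumps(
                {
                    "intervention": {
                        "cost": self.scenario.intervention.total_discounted_cost,
                        "qalys": self.scenario.intervention.total_discounted_qalys,
                    },
                    "control": {
                        "cost": self.scenario.control.total_discounted_cost,
                        "qalys": self.scenario.control.total_discounted_qalys,
                    },
                    "incremental": {
                        "delta_cost": inc.delta_cost,
                        "delta_qalys": inc.delta_qalys,
                        "icer": inc.icer,
                        "verdict": inc.verdict,
                        "nmb": inc.nmb,
                        "lambda": inc.wtp_lambda,
                    },
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        paths.append(summary_path)
        return paths


def run_base_case(
    params: ParameterSet, wtp_lambda: float | None = None
) -> BaseCaseReport:
    """Run both arms at base-case values and assemble the results table."""
    lam = params.run.wtp_lambda if wtp_lambda is None else wtp_lambda
    return BaseCaseReport(scenario=run_scenario(params, lam), wtp_lambda=lam)


def make_figures(psa_dir: str | Path, outdir: str | Path | None = None) -> list[Path]:
    """Draw the CE-plane scatter and the CEAC from a PSA output directory.

    Figures are regenerable artifacts: they are drawn purely from
    ``ce_plane.csv`` and ``ceac.csv``, never from in-memory state.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    psa_dir = Path(psa_dir)
    outdir = psa_dir if outdir is None else Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plane_csv = psa_dir / "ce_plane.csv"
    ceac_csv = psa_dir / "ceac.csv"
    for p in (plane_csv, ceac_csv):
        if not p.exists():
            raise DvaCeaError(f"missing PSA output file: {p}")

    plane = pd.read_csv(plane_csv)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["delta_qalys"], plane["delta_cost"], s=8, alpha=0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title("Cost-effectiveness plane")
    plane_png = outdir / "ce_plane.png"
    fig.savefig(plane_png, dpi=150, bbox_inches="tight")
    plt.close(fig)

    ceac = pd.read_csv(ceac_csv)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["lambda"], ceac["probability"])
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    ceac_png = outdir / "ceac.png"
    fig.savefig(ceac_png, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [plane_png, ceac_png]


@dataclass
class RunManifest:
    """Provenance record for one command invocation."""

    command: str
    config_digest: str
    seed: int | None
    outputs: list[str]
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "config_digest": self.config_digest,
                    "seed": self.seed,
                    "outputs": self.outputs,
                    "version": self.version,
                    "timestamp": self.timestamp,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        return path


def config_digest(path: str | Path) -> str:
    """SHA-256 of the configuration file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
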