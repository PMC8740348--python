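"""Report writers: CSV/JSON exports of outcomes, frontier, delay-loss,
tornado, PSA draws and CEAC, plus a run manifest.

CSV files use display rounding matched to the published table granularity
(costs and ICERs to whole CNY, QALYs to 2 d.p.); JSON files keep full
precision.  The manifest lists every file written and is written last.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import pandas as pd

from .frontier import DelayLossMetrics, FrontierResult
from .markov import StrategyOutcome
from .sensitivity import CEACCurve, PSAResult, TornadoEntry, tornado_frame


def _pkg_version() -> str:
    try:
        return version("evtdelay")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


class ReportWriter:
    """Accumulates output files under one directory and writes the manifest."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        if not self.outdir.is_dir():
            raise NotADirectoryError(str(self.outdir))
        self.files: list[str] = []

    def _register(self, path: Path) -> Path:
        self.files.append(path.name)
        return path

    def write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self._register(self.outdir / name)
        df.to_csv(path, index=False)
        return path

    def write_json(self, obj, name: str) -> Path:
        path = self._register(self.outdir / name)
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        return path

    def write_outcomes(self, outcomes: Sequence[StrategyOutcome]) -> None:
        df = pd.DataFrame(
            {
                "window": [o.label for o in outcomes],
                "midpoint_min": [o.window.midpoint_min for o in outcomes],
                "cost": [round(o.total_cost) for o in outcomes],
                "qaly": [round(o.total_qaly, 2) for o in outcomes],
            }
        )
        self.write_csv(df, "outcomes.csv")
        self.write_json(
            {
                o.label: {"cost": o.total_cost, "qaly": o.total_qaly}
                for o in outcomes
            },
            "outcomes.json",
        )

    def write_frontier(self, result: FrontierResult) -> None:
        df = result.to_frame()
        disp = df.copy()
        for col in ("cost", "incremental_cost", "icer", "inmb"):
            disp[col] = disp[col].round(0)
        for col in ("qaly", "incremental_qaly"):
            disp[col] = disp[col].round(2)
        self.write_csv(disp, "frontier.csv")
        self.write_json(
            {"wtp": result.wtp, "rows": df.to_dict(orient="records")},
            "frontier.json",
        )

    def write_delay_loss(self, metrics: DelayLossMetrics) -> None:
        d = metrics.to_dict()
        self.write_csv(
            pd.DataFrame({"metric": list(d), "value": list(d.values())}),
            "delay_loss.csv",
        )
        self.write_json(d, "delay_loss.json")

    def write_tornado(self, entries: Sequence[TornadoEntry]) -> None:
        df = tornado_frame(entries)
        self.write_csv(df, "tornado.csv")
        self.write_json(df.to_dict(orient="records"), "tornado.json")

    def write_psa(self, psa: PSAResult) -> None:
        self.write_csv(psa.to_frame(), "psa_draws.csv")

    def write_ceac(self, curve: CEACCurve) -> None:
        self.write_csv(curve.to_frame(), "ceac.csv")
        self.write_json(
            {
                "wtp": list(curve.wtp_grid),
                "probabilities": {
                    lb: list(curve.probabilities[:, j])
                    for j, lb in enumerate(curve.labels)
                },
            },
            "ceac.json",
        )

    def write_manifest(
        self, subcommand: str, config_source: str, seeds: dict[str, int] | None = None
    ) -> Path:
        manifest = {
            "subcommand": subcommand,
            "config": config_source,
            "seeds": seeds or {},
            "output_dir": str(self.outdir),
            "outputs": sorted(self.files),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "package_version": _pkg_version(),
        }
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n")
        return path
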