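"""End-to-end pipeline: dataset -> CRPs, CRQA tables, composite panels.

For every target record (by default each factor at the center station)
the pipeline builds one candidate panel per station, writes the CRQA
table, the composite score table and a heatmap, optionally renders each
pair's CRP, runs the record-length sensitivity study for the first
target, and logs every parameter used (including the absolute epsilon
per pair) to ``params.json``.  Any stage failure removes the partial
outputs of this run and raises a stage-named :class:`PipelineError`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .composite import (
    CouplingPanel,
    build_panel,
    length_sensitivity,
    normalize_panels,
    render_heatmap,
)
from .config import PipelineConfig
from .cross_recurrence import render_crp
from .io import StationDataset, read_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    out_dir: Path
    panels: dict  # target -> list[CouplingPanel], normalized
    files: list[Path] = field(default_factory=list)


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in name)


def run_pipeline(
    data: StationDataset | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "hydrorqa_out",
) -> PipelineResult:
    cfg = (config or PipelineConfig()).validate()
    out = Path(out_dir)
    created: list[Path] = []
    stage = "load"
    try:
        dataset = (
            data
            if isinstance(data, StationDataset)
            else read_dataset(data, max_gap=cfg.max_gap)
        )
        if len(dataset.series) < 2:
            raise ValueError("need >=2 series (at least two stations or two factors)")
        out.mkdir(parents=True, exist_ok=True)

        stage = "targets"
        center = cfg.center_station or dataset.stations[0]
        if center not in dataset.stations:
            raise ValueError(f"center station {center!r} not in dataset")
        targets = cfg.targets or [(center, f) for f in dataset.factors]

        params_cache: dict = {}
        epsilon_log: list[dict] = []
        panels_by_target: dict[tuple[str, str], list[CouplingPanel]] = {}

        for target in targets:
            stage = f"panel {target[0]}:{target[1]}"
            tdir = out / _safe(f"{target[0]}_{target[1]}")
            tdir.mkdir(exist_ok=True)
            raw_panels = []
            for station in dataset.stations:
                candidates = [
                    (station, f) for f in dataset.factors if f != target[1]
                ]
                if not candidates:
                    continue

                def hook(matrix, cand, _tdir=tdir):
                    epsilon_log.append(
                        {
                            "target": f"{target[0]}:{target[1]}",
                            "other": f"{cand[0]}:{cand[1]}",
                            "epsilon": matrix.epsilon,
                            "epsilon_fraction": matrix.epsilon_fraction,
                            "norm": matrix.norm,
                            "shape": list(matrix.shape),
                        }
                    )
                    if cfg.render_crps:
                        p = _tdir / (_safe(f"crp_{cand[0]}_{cand[1]}") + ".png")
                        render_crp(matrix, p)
                        created.append(p)

                raw_panels.append(
                    build_panel(
                        target,
                        candidates,
                        dataset,
                        cfg,
                        params_cache=params_cache,
                        matrix_hook=hook,
                    )
                )
            panels = normalize_panels(
                raw_panels, scope=cfg.normalization_scope, floor=cfg.score_floor
            )
            panels_by_target[target] = panels

            stage = f"tables {target[0]}:{target[1]}"
            raw = pd.concat([p.table for p in panels], ignore_index=True)
            crqa_table = raw[["station", "factor", "mdl", "rr", "det", "lam"]].rename(
                columns={"mdl": "MDL", "rr": "RR", "det": "DET", "lam": "LAM"}
            )
            p_crqa = tdir / "crqa.csv"
            crqa_table.to_csv(p_crqa, index=False)
            created.append(p_crqa)

            composite = raw[["station", "factor", "rr", "det", "lam", "mdl", "mi"]].rename(
                columns=str.upper
            ).rename(columns={"STATION": "station", "FACTOR": "factor"})
            composite["score"] = pd.concat(
                [p.scores for p in panels], ignore_index=True
            )
            p_comp = tdir / "composite.csv"
            composite.to_csv(p_comp, index=False)
            created.append(p_comp)

            p_heat = tdir / "heatmap.png"
            render_heatmap(panels, p_heat)
            created.append(p_heat)

        if cfg.lengths:
            stage = "length-sensitivity"
            target = targets[0]
            rows = []
            for station in dataset.stations:
                candidates = [(station, f) for f in dataset.factors if f != target[1]]
                if not candidates:
                    continue
                sens = length_sensitivity(
                    dataset, target, candidates, cfg.lengths, cfg
                )
                tab = sens.scores.reset_index()
                for L in sens.lengths:
                    tab[f"spearman_{L}"] = sens.spearman[L]
                rows.append(tab)
            p_sens = out / "length_sensitivity.csv"
            pd.concat(rows, ignore_index=True).to_csv(p_sens, index=False)
            created.append(p_sens)

        stage = "log"
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()
            },
            "targets": [list(t) for t in targets],
            "embedding_params": {
                f"{k[0]}:{k[1]}": str(v) for k, v in params_cache.items()
            },
            "pairs": epsilon_log,
        }
        p_log = out / "params.json"
        p_log.write_text(json.dumps(payload, indent=2))
        created.append(p_log)

        return PipelineResult(out, panels_by_target, created)
    except Exception as exc:
        for path in created:
            try:
                path.unlink(missing_ok=True)
            except OSError:  # pragma: no cover
                pass
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
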