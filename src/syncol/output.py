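"""Serialization of simulation results: axial-profile CSVs, metrics and
run-metadata JSON.  Output is deterministic (fixed field order, 12
significant digits) so identical runs produce byte-identical artifacts
suitable for diff-based regression tests."""

from __future__ import annotations

import json
from pathlib import Path

from .simulator import SimulationResult, steady_state_metrics

__all__ = ["write_profiles", "write_metrics", "read_metrics", "PROFILE_HEADER"]

PROFILE_HEADER = (
    "z_m,X_gL,CO_L_mM,H2_L_mM,CO2_L_mM,EtOH_gL,Ac_gL,CO_G_mM,H2_G_mM,CO2_G_mM"
)
_FMT = "%.12g"


def _profile_csv(z, state) -> str:
    lines = [PROFILE_HEADER]
    for j in range(len(z)):
        row = [z[j]] + [state.fields[i, j] for i in range(9)]
        lines.append(",".join(_FMT % v for v in row))
    return "\n".join(lines) + "\n"


def write_profiles(result: SimulationResult, outdir: str | Path) -> list[Path]:
    """One CSV of the nine axial profiles per stored snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, t in enumerate(result.times):
        path = outdir / ("profile_t%g.csv" % t)
        path.write_text(_profile_csv(result.z, result.state_at(i)))
        written.append(path)
    return written


def write_metrics(
    result: SimulationResult,
    outdir: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Steady-state metrics as JSON plus a run-metadata echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = steady_state_metrics(result)
    path = outdir / "metrics.json"
    path.write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n")
    meta = {
        "steady_residual": result.steady_residual,
        "lp_infeasible_nodes": result.lp_infeasible_nodes,
        "n_rhs_evaluations": result.n_rhs_evaluations,
        "inlet_gas_mM": result.inlet_gas,
        "fresh_feed_mM": result.fresh_feed,
        "settings": {
            "final_time": result.settings.final_time,
            "n_nodes": result.settings.n_nodes,
            "rtol": result.settings.rtol,
            "atol": result.settings.atol,
            "steady_threshold": result.settings.steady_threshold,
            "scheme": result.settings.scheme,
            "seed": result.settings.seed,
        },
    }
    if metadata:
        meta.update(metadata)
    (outdir / "metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_metrics(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "metrics.json").read_text())
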