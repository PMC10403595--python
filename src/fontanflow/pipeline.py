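"""Case-matrix orchestration and comparison utilities.

Runs geometry variants x cardiac outputs end-to-end (mesh -> steady flow ->
dye transport -> endpoints), collects one report row per case, and offers
Bland-Altman / correlation statistics against externally supplied reference
measurements (e.g. a mock-loop pressure-drop table).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CaseConfig, config_hash
from .endpoints import endpoint_report
from .geometry import make_junction
from .solver import BCSet, run_steady
from .transport import (init_dye_cube, mean_washout,
                        solve_advection_diffusion, washout_time)
from .units import lmin_to_cm3s

log = logging.getLogger("fontanflow")

#: Reynolds numbers reported for the mock-loop inflow conditions (IVC limb,
#: D = 1.91 cm), attached to the Reynolds table purely as annotation: they
#: are not reproduced exactly by Re = 4 rho Q / (pi D mu) at the stated
#: fluid properties and 60/40 split, and the table reports its own values.
REPORTED_REYNOLDS = {3.0: 674, 5.0: 1015, 7.0: 1433, 9.0: 1839, 11.0: 2250}


def case_label(variant: str, co: float) -> str:
    return f"{variant}_co{co:g}"


def run_single_case(cfg: CaseConfig, variant: str, co: float,
                    mesh=None, out_dir=None) -> dict:
    """Mesh -> flow -> (transport) -> endpoint row for one case.

    With ``out_dir`` set, the final velocity/pressure (and dye) snapshots
    are archived as VTU next to the reports.
    """
    if mesh is None:
        mesh = make_junction(cfg.variant_geometry(variant), cfg.sizing,
                             seed=cfg.seed)
    q_total = lmin_to_cm3s(co)
    bcs = BCSet(
        inlet_flows={"inlet_ivc": cfg.ivc_fraction * q_total,
                     "inlet_svc": (1.0 - cfg.ivc_fraction) * q_total},
        outlet_resistances=dict(cfg.outlet_resistances),
        wall_tags=tuple(t for t in mesh.tags if t.startswith("wall")),
    )
    field = run_steady(mesh, cfg.fluid, bcs, cfg.solver)
    if field.status.get("failed"):
        raise RuntimeError(f"flow solve failed: {field.status.get('error')}")
    washout = None
    if cfg.run_transport:
        dye0 = init_dye_cube(mesh, cfg.dye.center, cfg.dye.side)
        series = solve_advection_diffusion(
            mesh, field.velocities[-1], dye0, cfg.transport)
        wf = washout_time(series, cfg.dye.threshold)
        washout = mean_washout(wf, mesh, region=dye0.phi > 0.5)
    if out_dir is not None:
        from .io import write_vtu_snapshot
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data = {"velocity": field.velocities[-1],
                "pressure": field.pressures[-1]}
        if cfg.run_transport:
            data["dye"] = series.phis[-1]
        write_vtu_snapshot(mesh, out / f"{case_label(variant, co)}.vtu",
                           data)
    row = endpoint_report(field, cfg.fluid, cfg.solver.averaging_window,
                          washout=washout)
    row["case"] = case_label(variant, co)
    row["variant"] = variant
    row["co_lmin"] = co
    row["stationary"] = bool(field.status.get("converged", False))
    row["n_nodes"] = mesh.n_nodes
    return row


def run_case_matrix(cfg: CaseConfig, out_dir=None) -> pd.DataFrame:
    """Run every variant x CO; per-case failures are recorded, not fatal.

    Meshes are built once per variant and reused across cardiac outputs.
    Writes ``report.csv``, ``report.json`` and a run manifest when an
    output directory is given.
    """
    out = Path(out_dir or cfg.output_dir)
    rows = []
    for variant in cfg.variants:
        try:
            mesh = make_junction(cfg.variant_geometry(variant), cfg.sizing,
                                 seed=cfg.seed)
        except Exception as exc:
            log.error("meshing failed for %s: %s", variant, exc)
            for co in cfg.cardiac_outputs:
                rows.append({"case": case_label(variant, co),
                             "variant": variant, "co_lmin": co,
                             "failed": True, "error": str(exc)})
            continue
        for co in cfg.cardiac_outputs:
            label = case_label(variant, co)
            log.info("running case %s", label)
            try:
                row = run_single_case(cfg, variant, co, mesh=mesh,
                                      out_dir=out if cfg.save_fields
                                      else None)
                row["failed"] = False
                rows.append(row)
            except Exception as exc:
                log.error("case %s failed: %s", label, exc)
                log.debug("%s", traceback.format_exc())
                rows.append({"case": label, "variant": variant,
                             "co_lmin": co, "failed": True,
                             "error": str(exc)})
    frame = pd.DataFrame(rows).set_index("case")
    if out_dir is not None or cfg.output_dir:
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "report.csv")
        frame.reset_index().to_json(out / "report.json", orient="records",
                                    indent=1)
        manifest = {"config_hash": config_hash(cfg),
                    "config": dataclasses.asdict(cfg),
                    "n_cases": len(frame)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
    return frame


# ----------------------------------------------------------------------
# comparison statistics
# ----------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Bland-Altman agreement between simulated and reference values.

    Limits of agreement use the sample standard deviation (n-1 in the
    denominator).
    """

    labels: list
    sim: np.ndarray
    ref: np.ndarray
    differences: np.ndarray
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    pearson_r: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "sim": self.sim,
                             "ref": self.ref, "diff": self.differences})


def bland_altman(sim, ref, labels=None) -> ComparisonTable:
    """Bland-Altman statistics for paired simulation/reference values."""
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sim.shape != ref.shape or sim.ndim != 1:
        raise ValueError("sim and ref must be equal-length 1-D sequences")
    if len(sim) < 2:
        raise ValueError("need at least 2 pairs")
    labels = list(labels) if labels is not None else \
        [str(i) for i in range(len(sim))]
    if len(labels) != len(sim):
        raise ValueError("labels length mismatch")
    diff = sim - ref
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(sim, sim[0]) or np.allclose(ref, ref[0]):
        r = np.nan
    else:
        r = float(np.corrcoef(sim, ref)[0, 1])
    return ComparisonTable(
        labels=labels, sim=sim, ref=ref, differences=diff,
        mean_difference=mean_diff, sd_difference=sd,
        loa_lower=mean_diff - 1.96 * sd, loa_upper=mean_diff + 1.96 * sd,
        pearson_r=r)


def bland_altman_plot(table: ComparisonTable, path) -> None:
    """Bland-Altman and correlation panels, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    means = 0.5 * (table.sim + table.ref)
    ax1.scatter(means, table.differences, s=18)
    for y, style in ((table.mean_difference, "-"),
                     (table.loa_lower, "--"), (table.loa_upper, "--")):
        ax1.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax1.set_xlabel("mean of simulation and reference")
    ax1.set_ylabel("simulation - reference")
    ax1.set_title("Bland-Altman")
    lim = [min(table.ref.min(), table.sim.min()),
           max(table.ref.max(), table.sim.max())]
    ax2.plot(lim, lim, "k--", linewidth=0.8)
    ax2.scatter(table.ref, table.sim, s=18)
    ax2.set_xlabel("reference")
    ax2.set_ylabel("simulation")
    ax2.set_title(f"correlation (r = {table.pearson_r:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reynolds_report(cfg: CaseConfig, diameter: float = 1.91) -> pd.DataFrame:
    """Per-case Reynolds numbers, Re = 4 rho Q_ivc / (pi D mu).

    The reported reference values are attached as an annotation column;
    they differ from the formula at the stated properties (see module
    constant), and this table deliberately reports its own numbers.
    """
    rows = []
    rho, mu = cfg.fluid.density, cfg.fluid.viscosity
    for co in cfg.cardiac_outputs:
        q_ivc = cfg.ivc_fraction * lmin_to_cm3s(co)
        re = 4.0 * rho * q_ivc / (np.pi * diameter * mu)
        rows.append({"co_lmin": co, "q_ivc_cm3s": q_ivc,
                     "reynolds": re,
                     "reported_reference": REPORTED_REYNOLDS.get(co)})
    return pd.DataFrame(rows)
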