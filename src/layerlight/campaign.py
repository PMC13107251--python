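"""Campaign runner: layered sweeps of recovered effective absorption changes.

A sweep walks a grid of top-layer thickness L1 and one varied optical
parameter of the superficial layer, and for every grid point runs the full
chain: white Monte Carlo -> baseline complex reflectance -> self-calibrated
homogeneous fit -> deep-layer absorption perturbation (default 0.001 mm^-1)
-> effective Delta mua_M for the six data types.

Because the Monte Carlo is white (absorption applied by re-weighting), a
single ledger per geometry-and-scattering configuration serves the entire
absorption grid exactly; only mus' or thickness changes force a new
simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .engine import DATA_TYPES, compute_datatypes, delta_datatypes, fit_absolute_properties, retrieve_dmua
from .forward import OMEGA_DEFAULT, assemble_reflectance, homogeneous_jacobian
from .media import make_ds_array, make_three_layer, make_two_layer
from .mc import run_white_mc

__all__ = ["SweepSpec", "run_campaign", "run_point", "export_results", "fit_ledger_baseline"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for one campaign.

    ``varied`` is the parameter swept at each L1: "mua1" (re-weighted on a
    shared ledger), "musp1" (new simulation per value) or "none".
    ``constants`` holds the remaining medium parameters understood by
    :func:`~layerlight.media.make_two_layer` /
    :func:`~layerlight.media.make_three_layer`.
    """

    model: str  # "two-layer" | "three-layer"
    l1_grid: tuple = (8.0, 10.0, 12.0, 14.0, 16.0)
    varied: str = "mua1"
    values: tuple = ()
    constants: dict = field(default_factory=dict)
    n_photons: int = 10_000_000
    seed: int = 0
    omega: float = OMEGA_DEFAULT
    tally_mode: str = "annular"
    delta_deep: float = 0.001
    delta_superficial: float = 0.0
    max_path: float = 2000.0

    def __post_init__(self) -> None:
        if self.model not in ("two-layer", "three-layer"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.varied not in ("mua1", "musp1", "none"):
            raise ValueError(f"unknown varied parameter {self.varied!r}")
        if len(self.l1_grid) == 0 or (self.varied != "none" and len(self.values) == 0):
            raise ValueError("empty grid")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=float).encode()
        ).hexdigest()[:12]


def _build_medium(model: str, L1: float, params: dict):
    if model == "two-layer":
        return make_two_layer(
            L1,
            mua1=params["mua1"],
            mua2=params["mua2"],
            musp1=params["musp1"],
            musp2=params["musp2"],
        )
    return make_three_layer(
        L1,
        L2=params.get("L2", 2.0),
        mua1=params["mua1"],
        mua2=params.get("mua2_csf", 0.0027),
        mua3=params["mua3"],
        musp1=params["musp1"],
        musp2=params.get("musp2_csf", 0.01),
        musp3=params["musp3"],
    )


def fit_ledger_baseline(ledger, mua_per_layer, omega: float = OMEGA_DEFAULT):
    """Baseline data types and homogeneous fit for a ledger."""
    refl = assemble_reflectance(ledger, mua_per_layer, omega)
    dtv = compute_datatypes(refl)
    props = fit_absolute_properties(dtv, omega)
    return dtv, props


def run_point(
    ledger,
    mua_per_layer,
    delta_mua_per_layer,
    omega: float = OMEGA_DEFAULT,
) -> dict:
    """One grid point: fit baseline, perturb, retrieve all six Delta mua_M."""
    mua = np.asarray(mua_per_layer, float)
    delta = np.asarray(delta_mua_per_layer, float)
    base_dtv, props = fit_ledger_baseline(ledger, mua, omega)
    pert_dtv = compute_datatypes(assemble_reflectance(ledger, mua + delta, omega))
    dM = delta_datatypes(base_dtv, pert_dtv)
    jac = homogeneous_jacobian(props.mua, props.musp, omega)
    dmua = retrieve_dmua(dM, jac)
    return {
        "fit_mua": props.mua,
        "fit_musp": props.musp,
        "converged": props.converged,
        "dmua": {m: dmua[m].dmua for m in DATA_TYPES},
        "dmua_se": {m: dmua[m].standard_error for m in DATA_TYPES},
    }


def run_campaign(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Run the sweep; returns one row per (grid point, data type).

    A Monte Carlo failure at one grid point flags its rows and the campaign
    continues.  Identical spec and seed give identical output tables.
    """
    optodes = make_ds_array()
    values = spec.values if spec.varied != "none" else (None,)
    rows = []
    run_idx = 0
    for L1 in spec.l1_grid:
        ledger = None
        ledger_key = None
        for val in values:
            params = dict(spec.constants)
            if spec.varied != "none" and val is not None:
                params[spec.varied] = val
            # one white ledger serves every absorption assignment at this
            # (L1, scattering) configuration
            key = (L1, params.get("musp1"))
            try:
                if ledger is None or key != ledger_key:
                    medium = _build_medium(spec.model, L1, params)
                    run_seed = (spec.seed * 1_000_003 + run_idx * 7919) % (2**31)
                    run_idx += 1
                    ledger = run_white_mc(
                        medium,
                        optodes,
                        spec.n_photons,
                        seed=run_seed,
                        tally_mode=spec.tally_mode,
                        max_path=spec.max_path,
                    )
                    ledger_key = key
                    if progress:
                        print(f"  MC done: L1={L1} {spec.varied}={val} "
                              f"({len(ledger)} detected)")
                medium = _build_medium(spec.model, L1, params)
                delta = np.zeros(medium.n_layers)
                delta[-1] = spec.delta_deep
                delta[0] += spec.delta_superficial
                res = run_point(ledger, medium.mua, delta, spec.omega)
                for m in DATA_TYPES:
                    rows.append(
                        {
                            "model": spec.model,
                            "L1_mm": L1,
                            "varied": spec.varied,
                            "value": val,
                            "data_type": m,
                            "dmua_M": res["dmua"][m],
                            "dmua_M_se": res["dmua_se"][m],
                            "fit_mua": res["fit_mua"],
                            "fit_musp": res["fit_musp"],
                            "converged": res["converged"],
                            "delta_deep": spec.delta_deep,
                            "delta_superficial": spec.delta_superficial,
                            "n_photons": spec.n_photons,
                            "seed": spec.seed,
                            "error": "",
                        }
                    )
            except Exception as exc:  # flag and continue
                for m in DATA_TYPES:
                    rows.append(
                        {
                            "model": spec.model,
                            "L1_mm": L1,
                            "varied": spec.varied,
                            "value": val,
                            "data_type": m,
                            "dmua_M": np.nan,
                            "dmua_M_se": np.nan,
                            "fit_mua": np.nan,
                            "fit_musp": np.nan,
                            "converged": False,
                            "delta_deep": spec.delta_deep,
                            "delta_superficial": spec.delta_superficial,
                            "n_photons": spec.n_photons,
                            "seed": spec.seed,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
    return pd.DataFrame(rows)


def export_results(table: pd.DataFrame, basename, formats=("csv", "json"), spec: SweepSpec | None = None) -> list:
    """Write the campaign table as CSV and/or JSON with schema and provenance."""
    if len(table) == 0:
        raise ValueError("refusing to export an empty results table")
    written = []
    base = str(basename)
    if "csv" in formats:
        path = base + ".csv"
        table.to_csv(path, index=False)
        written.append(path)
    if "json" in formats:
        path = base + ".json"
        doc = {
            "schema_version": SCHEMA_VERSION,
            "config_hash": spec.config_hash() if spec is not None else None,
            "spec": asdict(spec) if spec is not None else None,
            "rows": table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)
        written.append(path)
    if not written:
        raise ValueError(f"no known format in {formats}")
    return written
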