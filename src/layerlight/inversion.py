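"""Layer-sensitivity matrix and least-squares separation of layer changes.

For a three-layer head model, the sensitivity of data type M to absorption
in layer i is the partial derivative dM/dmua_i normalised by the summed
derivative over *all* layers (the CSF layer participates in the
normalisation even though its absorption change is not solved for):

    S[M, i] = (dM/dmua_i) / (dM/dmua_1 + dM/dmua_2 + dM/dmua_3)

Stacking the six data types gives a 6 x 2 matrix over the retained layers
(superficial and cerebral).  A measurement vector of effective absorption
changes then factors as Delta mua_M = S @ (Delta mua_1, Delta mua_3), solved
in the least-squares sense with the Moore-Penrose pseudoinverse, with SEM
propagated element-wise under an uncorrelated-noise assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .engine import DATA_TYPES

__all__ = [
    "LayerSensitivity",
    "LayerAbsorptionSolution",
    "datatype_layer_derivatives",
    "build_sensitivity_matrix",
    "solve_layers",
    "propagate_sem",
]


def datatype_layer_derivatives(
    layer_derivs: dict, rhos: tuple[float, float] = (25.0, 37.0)
) -> np.ndarray:
    """(6, Nl) matrix of dM/dmua_j for the six data types of one DS set.

    ``layer_derivs`` maps ``(source, detector)`` to
    :class:`~layerlight.forward.LayerDerivatives`.  Intensity types pass
    through ln|R~| (the rho^2 factor drops out of the derivative), phase
    types through arg(R~); mirror pairs are averaged and slopes are
    two-point differences, mirroring :func:`~layerlight.engine.compute_datatypes`.
    """
    rho_s, rho_l = rhos
    per_source: dict = {}
    for (src, det), ld in layer_derivs.items():
        which = (
            "short" if np.isclose(ld.rho, rho_s)
            else "long" if np.isclose(ld.rho, rho_l)
            else None
        )
        if which is None:
            continue
        per_source.setdefault(src, {})[which] = ld
    if len(per_source) != 2 or any(set(v) != {"short", "long"} for v in per_source.values()):
        raise ValueError("need two sources with one short and one long channel each")
    srcs = sorted(per_source)
    nl = next(iter(layer_derivs.values())).dR_dmua.size
    dlnI = {k: per_source[s][w].dlnI_dmua for s in srcs for w, k in (("short", (s, "s")), ("long", (s, "l")))}
    dph = {k: per_source[s][w].dphase_dmua for s in srcs for w, k in (("short", (s, "s")), ("long", (s, "l")))}
    drho = rho_l - rho_s

    rows = np.zeros((6, nl))
    rows[0] = np.mean([dlnI[(s, "s")] for s in srcs], axis=0)  # sdi25
    rows[1] = np.mean([dlnI[(s, "l")] for s in srcs], axis=0)  # sdi37
    rows[2] = np.mean([dph[(s, "s")] for s in srcs], axis=0)  # sdphi25
    rows[3] = np.mean([dph[(s, "l")] for s in srcs], axis=0)  # sdphi37
    rows[4] = np.mean([(dlnI[(s, "l")] - dlnI[(s, "s")]) / drho for s in srcs], axis=0)
    rows[5] = np.mean([(dph[(s, "l")] - dph[(s, "s")]) / drho for s in srcs], axis=0)
    return rows


@dataclass(frozen=True)
class LayerSensitivity:
    """Normalized layer-sensitivity matrix for one DS set.

    ``S`` keeps only the retained layers (columns, default superficial and
    deepest); ``fractions`` keeps all layers (each row sums to 1 by
    construction); ``raw`` holds the unnormalized dM/dmua_j.
    """

    S: np.ndarray
    fractions: np.ndarray
    raw: np.ndarray
    retained_layers: tuple[int, ...]
    data_types: tuple[str, ...] = DATA_TYPES
    condition_number: float = np.nan
    provenance: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.S))

    @property
    def summed_jacobian(self) -> dict:
        """Row sums over all layers: the multi-layer J_M used to build
        measurement vectors from layered forward data."""
        sums = self.raw.sum(axis=1)
        return dict(zip(self.data_types, sums))

    def to_json(self, path) -> None:
        doc = {
            "data_types": list(self.data_types),
            "retained_layers": list(self.retained_layers),
            "S": self.S.tolist(),
            "fractions": self.fractions.tolist(),
            "raw": self.raw.tolist(),
            "condition_number": self.condition_number,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def build_sensitivity_matrix(
    layer_derivs: dict,
    rhos: tuple[float, float] = (25.0, 37.0),
    retained_layers: tuple[int, ...] | None = None,
    provenance: dict | None = None,
) -> LayerSensitivity:
    """Assemble the normalized 6 x 2 layer-sensitivity matrix.

    ``retained_layers`` defaults to the first and last layer (superficial
    and cerebral); the middle (CSF) column is dropped after normalisation.
    """
    raw = datatype_layer_derivatives(layer_derivs, rhos)
    nl = raw.shape[1]
    if retained_layers is None:
        retained_layers = (0, nl - 1)
    denom = raw.sum(axis=1)
    if np.any(np.abs(denom) < 1e-300):
        raise ValueError("zero summed derivative for at least one data type")
    fractions = raw / denom[:, None]
    S = fractions[:, list(retained_layers)]
    cond = float(np.linalg.cond(S))
    return LayerSensitivity(
        S=S,
        fractions=fractions,
        raw=raw,
        retained_layers=tuple(retained_layers),
        condition_number=cond,
        provenance=provenance or {},
    )


@dataclass(frozen=True)
class LayerAbsorptionSolution:
    dmua_layer1: float
    dmua_layer3: float
    sem_layer1: float
    sem_layer3: float
    residual_norm: float


def solve_layers(
    dmua_M,
    S: LayerSensitivity | np.ndarray,
    sem_vector=None,
) -> LayerAbsorptionSolution:
    """Least-squares separation of superficial and deep absorption changes.

    ``dmua_M`` is the 6-element measurement vector (ordered as
    :data:`~layerlight.engine.DATA_TYPES`), or a dict of
    :class:`~layerlight.engine.EffectiveAbsorptionChange` from
    :func:`~layerlight.engine.retrieve_dmua` (whose standard errors are then
    used when ``sem_vector`` is not given).
    """
    if isinstance(dmua_M, dict):
        vec = np.array([dmua_M[m].dmua for m in DATA_TYPES])
        if sem_vector is None:
            sem_vector = np.array([dmua_M[m].standard_error for m in DATA_TYPES])
    else:
        vec = np.asarray(dmua_M, float)
    mat = S.S if isinstance(S, LayerSensitivity) else np.asarray(S, float)
    if vec.shape != (mat.shape[0],):
        raise ValueError(f"measurement vector must have length {mat.shape[0]}")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(
            f"rank-deficient sensitivity matrix (cond={np.linalg.cond(mat):.3g})"
        )
    pinv = np.linalg.pinv(mat)
    sol = pinv @ vec
    resid = float(np.linalg.norm(mat @ sol - vec))
    if sem_vector is not None:
        sems = propagate_sem(mat, sem_vector)
    else:
        sems = (0.0, 0.0)
    return LayerAbsorptionSolution(
        dmua_layer1=float(sol[0]),
        dmua_layer3=float(sol[-1]),
        sem_layer1=float(sems[0]),
        sem_layer3=float(sems[-1]),
        residual_norm=resid,
    )


def propagate_sem(S, sem_vector) -> tuple[float, ...]:
    """SEM of the solved layer changes under uncorrelated measurement noise.

    var(Delta mua_L_i) = sum_M (S+[i, M])^2 sem_M^2.
    """
    mat = S.S if isinstance(S, LayerSensitivity) else np.asarray(S, float)
    sem = np.asarray(sem_vector, float)
    if np.any(sem < 0):
        raise ValueError("SEMs must be nonnegative")
    pinv = np.linalg.pinv(mat)
    return tuple(np.sqrt((pinv**2) @ sem**2))
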