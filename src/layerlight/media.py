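"""Layered media, dual-slope optode arrays, and the shared coordinate convention.

Coordinates: origin at source A on the top surface, z positive downward into
the tissue, optodes along +x.  All lengths are millimetres, all optical
coefficients mm^-1.  The simulation volume is a rectangular box (default
200 x 100 x 100 mm in x, y, z) whose top face (z = 0) carries the optodes;
the last layer fills the box to its full depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "OpticalLayer",
    "LayeredMedium",
    "DualSlopeSet",
    "OptodeArray",
    "make_two_layer",
    "make_three_layer",
    "make_homogeneous",
    "make_ds_array",
    "save_medium",
    "load_medium",
]

#: Default box extents (x, y, z) in mm.
DEFAULT_BOX = (200.0, 100.0, 100.0)

#: Default CSF-mimicking layer parameters (subarachnoid space).
CSF_THICKNESS = 2.0
CSF_MUA = 0.0027
CSF_MUSP = 0.01


@dataclass(frozen=True)
class OpticalLayer:
    """One horizontal tissue layer.

    Parameters
    ----------
    thickness : float
        Layer thickness in mm.  The deepest layer of a medium is extended to
        fill the simulation box.
    mua : float
        Absorption coefficient in mm^-1 (>= 0).
    musp : float
        Reduced scattering coefficient mus' = mus * (1 - g) in mm^-1.  Must be
        positive; values as low as 0.001 are accepted to represent clear,
        CSF-like layers.
    n : float
        Refractive index (default 1.4, an effective index for the
        scalp/skull/CSF/brain stack).
    g : float
        Scattering anisotropy in (-1, 1).  g = 0 (isotropic) is the default:
        in the diffusive regime only mus' matters, and isotropic sampling is
        several times cheaper.
    """

    thickness: float
    mua: float
    musp: float
    n: float = 1.4
    g: float = 0.0

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not self.musp >= 0.001:
            raise ValueError(f"musp must be >= 0.001 mm^-1, got {self.musp}")
        if self.n < 1:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if not -1 < self.g < 1:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")

    @property
    def mus(self) -> float:
        """Scattering coefficient mus = mus' / (1 - g) in mm^-1."""
        return self.musp / (1.0 - self.g)


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of :class:`OpticalLayer` (top first) inside a box."""

    layers: tuple[OpticalLayer, ...]
    box: tuple[float, float, float] = DEFAULT_BOX
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a medium needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        depth = self.box[2]
        upper = sum(l.thickness for l in self.layers[:-1])
        if upper >= depth:
            raise ValueError(
                f"layers above the deepest one span {upper} mm, "
                f"which exceeds the box depth {depth} mm"
            )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def boundaries(self) -> np.ndarray:
        """z of the layer interfaces: [0, z1, ..., box depth], length Nl + 1.

        The deepest layer is extended (or truncated) to the box depth.
        """
        z = np.concatenate(
            [[0.0], np.cumsum([l.thickness for l in self.layers])]
        )
        z[-1] = self.box[2]
        return z

    @property
    def mua(self) -> np.ndarray:
        return np.array([l.mua for l in self.layers])

    @property
    def musp(self) -> np.ndarray:
        return np.array([l.musp for l in self.layers])

    @property
    def n(self) -> np.ndarray:
        return np.array([l.n for l in self.layers])

    def with_mua(self, mua_per_layer) -> "LayeredMedium":
        """Copy of this medium with per-layer absorption replaced."""
        mua = np.broadcast_to(np.asarray(mua_per_layer, float), (self.n_layers,))
        layers = tuple(replace(l, mua=float(m)) for l, m in zip(self.layers, mua))
        return replace(self, layers=layers)

    def to_dict(self) -> dict:
        return {
            "box": list(self.box),
            "n_outside": self.n_outside,
            "layers": [
                {
                    "thickness": l.thickness,
                    "mua": l.mua,
                    "musp": l.musp,
                    "n": l.n,
                    "g": l.g,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredMedium":
        layers = tuple(OpticalLayer(**spec) for spec in d["layers"])
        return cls(
            layers=layers,
            box=tuple(d.get("box", DEFAULT_BOX)),
            n_outside=d.get("n_outside", 1.0),
        )


def make_two_layer(
    L1: float,
    mua1: float,
    mua2: float,
    musp1: float,
    musp2: float,
    *,
    n: float = 1.4,
    g: float = 0.0,
    box: tuple[float, float, float] = DEFAULT_BOX,
) -> LayeredMedium:
    """Two-layer head model: scalp+skull over (semi-infinite) cerebral tissue."""
    top = OpticalLayer(L1, mua1, musp1, n=n, g=g)
    if L1 >= box[2]:
        # Top layer fills the box: degenerates to a homogeneous medium.
        return LayeredMedium(layers=(top,), box=box)
    bottom = OpticalLayer(box[2] - L1, mua2, musp2, n=n, g=g)
    return LayeredMedium(layers=(top, bottom), box=box)


def make_three_layer(
    L1: float,
    L2: float = CSF_THICKNESS,
    mua1: float = 0.017,
    mua2: float = CSF_MUA,
    mua3: float = 0.021,
    musp1: float = 1.45,
    musp2: float = CSF_MUSP,
    musp3: float = 1.1,
    *,
    n: float = 1.4,
    g: float = 0.0,
    box: tuple[float, float, float] = DEFAULT_BOX,
) -> LayeredMedium:
    """Three-layer head model: scalp+skull / CSF-filled subarachnoid space / brain.

    Defaults for the middle layer are the CSF-mimicking values
    L2 = 2 mm, mua = 0.0027 mm^-1, mus' = 0.01 mm^-1.
    """
    if L1 + L2 >= box[2]:
        raise ValueError("L1 + L2 must be smaller than the box depth")
    return LayeredMedium(
        layers=(
            OpticalLayer(L1, mua1, musp1, n=n, g=g),
            OpticalLayer(L2, mua2, musp2, n=n, g=g),
            OpticalLayer(box[2] - L1 - L2, mua3, musp3, n=n, g=g),
        ),
        box=box,
    )


def make_homogeneous(
    mua: float,
    musp: float,
    *,
    n: float = 1.4,
    g: float = 0.0,
    box: tuple[float, float, float] = DEFAULT_BOX,
) -> LayeredMedium:
    """Single-layer medium filling the whole box."""
    return LayeredMedium(layers=(OpticalLayer(box[2], mua, musp, n=n, g=g),), box=box)


@dataclass(frozen=True)
class DualSlopeSet:
    """One dual-slope set: two sources and two detectors on a line.

    The four source-detector pairs realise two short and two long distances
    (defaults 25 and 37 mm).  Pairs at equal rho ("mirror pairs") are
    (source_a, det_1) / (source_b, det_2) at rho_short and
    (source_a, det_2) / (source_b, det_1) at rho_long.
    """

    source_a: int
    source_b: int
    det_1: int
    det_2: int
    rho_short: float = 25.0
    rho_long: float = 37.0

    def __post_init__(self) -> None:
        if np.isclose(self.rho_short, self.rho_long):
            raise ValueError(
                "rho_short == rho_long: slope over a single distance is undefined"
            )

    @property
    def rhos(self) -> tuple[float, float]:
        return (self.rho_short, self.rho_long)


@dataclass(frozen=True)
class OptodeArray:
    """Sources and detectors on the top surface, grouped into DS sets.

    ``sources`` and ``detectors`` are (N, 2) arrays of (x, y) positions in mm.
    """

    sources: np.ndarray
    detectors: np.ndarray
    detector_radius: float = 1.0
    ds_sets: tuple[DualSlopeSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", np.atleast_2d(np.asarray(self.sources, float)))
        object.__setattr__(self, "detectors", np.atleast_2d(np.asarray(self.detectors, float)))
        if self.detector_radius <= 0:
            raise ValueError("detector_radius must be positive")

    def distance(self, source: int, detector: int) -> float:
        return float(np.hypot(*(self.sources[source] - self.detectors[detector])))

    @property
    def distance_matrix(self) -> np.ndarray:
        """(n_sources, n_detectors) matrix of source-detector distances."""
        diff = self.sources[:, None, :] - self.detectors[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    @property
    def rhos(self) -> tuple[float, ...]:
        """Sorted unique nominal distances across all DS sets."""
        r = sorted({r for ds in self.ds_sets for r in ds.rhos})
        return tuple(r)

    def to_dict(self) -> dict:
        return {
            "sources": self.sources.tolist(),
            "detectors": self.detectors.tolist(),
            "detector_radius": self.detector_radius,
            "ds_sets": [
                {
                    "source_a": d.source_a,
                    "source_b": d.source_b,
                    "det_1": d.det_1,
                    "det_2": d.det_2,
                    "rho_short": d.rho_short,
                    "rho_long": d.rho_long,
                }
                for d in self.ds_sets
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptodeArray":
        return cls(
            sources=np.asarray(d["sources"], float),
            detectors=np.asarray(d["detectors"], float),
            detector_radius=d.get("detector_radius", 1.0),
            ds_sets=tuple(DualSlopeSet(**s) for s in d.get("ds_sets", [])),
        )


def make_ds_array(
    rho_short: float = 25.0,
    rho_long: float = 37.0,
    *,
    origin: tuple[float, float] = (0.0, 0.0),
    detector_radius: float = 1.0,
) -> OptodeArray:
    """Default collinear dual-slope set.

    Source A at the origin, detector 1 at ``rho_short``, detector 2 at
    ``rho_long``, and source B at ``rho_short + rho_long`` along +x, so that
    B->2 is short and B->1 is long.  The distance matrix is
    ``{A->1: 25, A->2: 37, B->1: 37, B->2: 25}`` mm by default.
    """
    ds = DualSlopeSet(0, 1, 0, 1, rho_short=rho_short, rho_long=rho_long)
    x0, y0 = origin
    sources = np.array([[x0, y0], [x0 + rho_short + rho_long, y0]])
    detectors = np.array([[x0 + rho_short, y0], [x0 + rho_long, y0]])
    return OptodeArray(
        sources=sources,
        detectors=detectors,
        detector_radius=detector_radius,
        ds_sets=(ds,),
    )


def save_medium(medium: LayeredMedium, path, optodes: OptodeArray | None = None) -> None:
    """Serialize a medium (and optionally an optode array) to YAML."""
    doc = {"medium": medium.to_dict()}
    if optodes is not None:
        doc["optodes"] = optodes.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_medium(path) -> tuple[LayeredMedium, OptodeArray | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    medium = LayeredMedium.from_dict(doc["medium"])
    optodes = OptodeArray.from_dict(doc["optodes"]) if "optodes" in doc else None
    return medium, optodes
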