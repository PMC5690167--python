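"""CyberKnife-like non-coplanar circular beam sets.

Source points are placed quasi-uniformly (Fibonacci lattice) on a spherical
cap of radius SAD about the target, restricted to directions that do not
enter through the couch: the cap is centered on the anterior axis (-y) and
bounded by a configurable polar angle.  Every beam axis passes through the
target point exactly; collimator diameters are assigned round-robin from the
configured list and initial MU weights are equal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Beam", "BeamSet", "generate_beamset", "FIXED_COLLIMATORS"]

#: the 12 fixed circular collimator diameters (mm)
FIXED_COLLIMATORS = (5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_ANTERIOR = np.array([0.0, -1.0, 0.0])  # polar axis of the allowed cap


@dataclass
class Beam:
    source: np.ndarray
    target: np.ndarray
    diameter: float
    mu: float = 1.0

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if np.allclose(self.source, self.target):
            raise ValueError("beam source and target coincide")
        if self.diameter <= 0:
            raise ValueError("collimator diameter must be positive")
        if self.mu < 0:
            raise ValueError("MU must be >= 0")

    @property
    def direction(self) -> np.ndarray:
        d = self.target - self.source
        return d / np.linalg.norm(d)

    @property
    def sad(self) -> float:
        return float(np.linalg.norm(self.target - self.source))


@dataclass
class BeamSet:
    beams: list[Beam]
    sad: float = 800.0

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError("SAD must be positive")

    def __len__(self) -> int:
        return len(self.beams)

    def __iter__(self):
        return iter(self.beams)

    def __getitem__(self, i: int) -> Beam:
        return self.beams[i]

    @property
    def total_mu(self) -> float:
        return float(sum(b.mu for b in self.beams))

    def with_mus(self, mus: np.ndarray) -> "BeamSet":
        mus = np.asarray(mus, dtype=float)
        if mus.shape != (len(self.beams),):
            raise ValueError("one MU per beam required")
        return BeamSet(
            [Beam(b.source.copy(), b.target.copy(), b.diameter, float(m))
             for b, m in zip(self.beams, mus)],
            self.sad,
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(sources, targets, diameters, mus) as contiguous arrays."""
        n = len(self.beams)
        src = np.empty((n, 3))
        tgt = np.empty((n, 3))
        dia = np.empty(n)
        mus = np.empty(n)
        for i, b in enumerate(self.beams):
            src[i], tgt[i], dia[i], mus[i] = b.source, b.target, b.diameter, b.mu
        return src, tgt, dia, mus

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "sad": self.sad,
            "beams": [
                {
                    "source": b.source.tolist(),
                    "target": b.target.tolist(),
                    "diameter": b.diameter,
                    "mu": b.mu,
                }
                for b in self.beams
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BeamSet":
        payload = json.loads(Path(path).read_text())
        beams = [
            Beam(np.array(b["source"]), np.array(b["target"]), b["diameter"], b["mu"])
            for b in payload["beams"]
        ]
        return cls(beams, payload["sad"])


def generate_beamset(
    n_beams: int,
    target,
    diameters,
    sad: float = 800.0,
    seed: int = 0,
    max_polar_deg: float = 100.0,
) -> BeamSet:
    """Quasi-uniform non-coplanar beam set aimed at ``target``.

    ``max_polar_deg`` is the polar-angle bound of the allowed cap measured
    from the anterior axis; 90 deg is exactly the anterior hemisphere, the
    default 100 deg adds a band of lateral-posterior obliques while keeping
    the inferior-posterior (through-couch) directions excluded.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    diameters = [float(d) for d in diameters]
    if not diameters:
        raise ValueError("diameter list must be non-empty")
    illegal = [d for d in diameters if d not in FIXED_COLLIMATORS]
    if illegal:
        raise ValueError(f"diameters {illegal} not in the fixed-collimator set {FIXED_COLLIMATORS}")
    target = np.asarray(target, dtype=float)

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)  # seed-dependent azimuthal twist

    c = np.cos(np.radians(max_polar_deg))
    # orthonormal basis with the anterior axis as pole
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    beams = []
    for k in range(n_beams):
        u = 1.0 - (1.0 - c) * (k + 0.5) / n_beams  # cos(polar), Fibonacci cap
        s = np.sqrt(max(0.0, 1.0 - u * u))
        phi = phi0 + k * _GOLDEN_ANGLE
        direction = u * _ANTERIOR + s * (np.cos(phi) * e1 + np.sin(phi) * e2)
        source = target + sad * direction
        beams.append(Beam(source, target.copy(), diameters[k % len(diameters)], 1.0))
    return BeamSet(beams, sad)
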