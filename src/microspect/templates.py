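"""Canonical microstate map templates on a schematic 10-20 layout.

The five classical resting-state maps are built analytically from a 2-D
schematic electrode layout (nose up, right ear at x = +1): two diagonal
gradients (A, B), an anterior-posterior gradient (C), a fronto-central
peak (D), and a centro-posterior peak (E). Each template is
average-referenced and unit-norm, so spatial correlation with a template
reduces to a dot product.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SCHEMATIC_1020", "CANONICAL_LABELS", "make_canonical_templates"]

#: Schematic 2-D positions (x = right, y = anterior) on the unit head circle.
SCHEMATIC_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "T7": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.00, 0.0),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.52), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# Older 10-20 names map onto the modern temporal/parietal labels.
_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

CANONICAL_LABELS = ("A", "B", "C", "D", "E")


def _positions(montage: list[str]) -> np.ndarray:
    pos = []
    for label in montage:
        key = _ALIASES.get(label, label)
        if key not in SCHEMATIC_1020:
            raise KeyError(f"unknown 10-20 channel label: {label!r}")
        pos.append(SCHEMATIC_1020[key])
    return np.asarray(pos, dtype=float)


def make_canonical_templates(
    n_channels: int = 19, montage: list[str] | None = None
) -> np.ndarray:
    """Build the five canonical map templates for a 10-20 montage.

    Returns a (5, n_channels) array ordered A-E; each row is
    average-referenced with unit L2 norm. Deterministic.
    """
    if montage is None:
        montage = list(SCHEMATIC_1020)
    if len(montage) != n_channels:
        raise ValueError(f"montage has {len(montage)} labels, expected {n_channels}")
    pos = _positions(montage)
    x, y = pos[:, 0], pos[:, 1]

    s2 = 2 * 0.55**2  # spatial width of the focal maps
    templates = np.stack(
        [
            (x + y) / np.sqrt(2),            # A: left-posterior / right-anterior
            (-x + y) / np.sqrt(2),           # B: mirror diagonal
            y,                               # C: anterior-posterior
            np.exp(-(x**2 + (y - 0.35) ** 2) / s2),  # D: fronto-central peak
            np.exp(-(x**2 + (y + 0.45) ** 2) / s2),  # E: centro-posterior peak
        ]
    )
    templates -= templates.mean(axis=1, keepdims=True)
    templates /= np.linalg.norm(templates, axis=1, keepdims=True)
    return templates
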