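"""Amphipathicity metrics for helical segments.

Mean hydrophobicity ⟨H⟩ and the Eisenberg hydrophobic moment μH on the
Fauchère–Pliska octanol/water scale, the convention used by helical-wheel
servers such as HeliQuest.  μH places residue n at angle n·δ around the
helix axis (δ = 100° per residue for an α-helix) and takes the
length-normalised vector norm of the per-residue hydrophobicities:

    μH = (1/N) · ‖ Σ_n H_n · (cos nδ, sin nδ) ‖

⟨H⟩ is permutation-invariant; μH is not (it measures the segregation of
hydrophobic residues onto one helix face).  Values are reported to two
decimals for display; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAUCHERE_PLISKA",
    "HelixSegment",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "analyze_segment",
]

# Fauchère & Pliska (1983) octanol/water transfer free energies as
# tabulated by HeliQuest; glycine is the scale's zero.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

ALPHA_HELIX_DELTA = 100.0  # degrees of helical twist per residue


@dataclass
class HelixSegment:
    sequence: str
    start: int
    end: int
    mean_h: float
    mu_h: float
    twist_delta: float = ALPHA_HELIX_DELTA


def _values(seq: str) -> np.ndarray:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    try:
        return np.array([FAUCHERE_PLISKA[c] for c in seq])
    except KeyError as e:
        raise ValueError(
            f"nonstandard residue {e.args[0]!r} in sequence {seq!r}"
        ) from None


def mean_hydrophobicity(seq: str) -> float:
    """Arithmetic mean of per-residue Fauchère–Pliska hydrophobicities."""
    return float(_values(seq).mean())


def hydrophobic_moment(seq: str, delta: float = ALPHA_HELIX_DELTA) -> float:
    """Length-normalised hydrophobic moment μH at twist ``delta`` degrees."""
    h = _values(seq)
    angles = np.deg2rad(delta) * np.arange(len(h))
    vec = (h * np.exp(1j * angles)).sum()
    return float(np.abs(vec) / len(h))


def analyze_segment(seq: str, start: int = 1,
                    delta: float = ALPHA_HELIX_DELTA) -> HelixSegment:
    seq = seq.strip().upper()
    return HelixSegment(
        sequence=seq,
        start=start,
        end=start + len(seq) - 1,
        mean_h=mean_hydrophobicity(seq),
        mu_h=hydrophobic_moment(seq, delta),
        twist_delta=delta,
    )
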