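"""Core in-memory data model for predicted protein complexes.

A predicted complex is represented as a :class:`ComplexModel` (chains,
residues, atom coordinates, per-residue pLDDT) plus a
:class:`ConfidenceBundle` (the PAE matrix and the pTM/ipTM summary values
emitted by the predictor).  :func:`attach` pairs the two into a
:class:`PairedModel`, which fixes the global residue indexing used by every
downstream score: 0-based internally, contiguous across chains in model
chain order; user-facing output is always 1-based with a chain id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PAE_MAX = 35.0  # Å; larger entries are treated as corrupt (unit error)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common modified residues mapped to their parent; anything else is dropped.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "MLY": "LYS",
}


class Atom(NamedTuple):
    name: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    """One amino-acid residue: 1-based index within its chain, 3-letter
    name, atom list and pLDDT in [0, 100]."""

    index: int
    name: str
    atoms: list[Atom]
    plddt: float = 0.0

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def atom_coord(self, name: str) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == name:
                return np.array([a.x, a.y, a.z], dtype=float)
        return None

    def cb_coord(self) -> np.ndarray | None:
        """Cβ coordinate (Cα for glycine) used for contact definitions."""
        if self.name != "GLY":
            cb = self.atom_coord("CB")
            if cb is not None:
                return cb
        return self.atom_coord("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue indices not strictly increasing"
            )
        for r in self.residues:
            if not (0.0 <= r.plddt <= 100.0):
                raise ValueError(
                    f"chain {self.chain_id} residue {r.index}: pLDDT {r.plddt} outside [0, 100]"
                )
            xyz = r.coords()
            if xyz.size and not np.all(np.isfinite(xyz)):
                raise ValueError(
                    f"chain {self.chain_id} residue {r.index}: non-finite coordinates"
                )


@dataclass
class ComplexModel:
    """A predicted complex: ordered chains of residues with coordinates and
    per-residue pLDDT."""

    model_id: str
    chains: list[Chain]
    source_method: str = "synthetic"  # af2m | af3 | apd2 | synthetic

    def validate(self) -> "ComplexModel":
        if not self.chains:
            raise ValueError(f"model {self.model_id}: no protein chains")
        for ch in self.chains:
            ch.validate()
        return self

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"model {self.model_id}: no chain {chain_id!r}")

    def plddt_array(self) -> np.ndarray:
        return np.array(
            [r.plddt for c in self.chains for r in c.residues], dtype=float
        )


@dataclass
class ConfidenceBundle:
    """PAE matrix plus pTM/ipTM summaries for one model.

    ``residue_chain`` maps the global (0-based) residue index to
    ``(chain_id, within-chain 1-based index)``; its order defines the PAE
    row/column order.  ``plddt`` is the optional per-residue pLDDT from the
    confidence file, which takes precedence over structure B-factors.
    """

    pae: np.ndarray
    residue_chain: list[tuple[str, int]]
    ptm: float | None = None
    iptm: float | None = None
    chain_pair_iptm: Mapping[tuple[str, str], float] | None = None
    plddt: np.ndarray | None = None

    def validate(self) -> "ConfidenceBundle":
        pae = np.asarray(self.pae, dtype=float)
        if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
            raise ValueError(f"PAE matrix is not square: shape {pae.shape}")
        if pae.shape[0] != len(self.residue_chain):
            raise ValueError(
                f"PAE dimension {pae.shape[0]} != residue map length {len(self.residue_chain)}"
            )
        if pae.size and (pae.min() < 0.0 or pae.max() > PAE_MAX):
            raise ValueError(
                f"PAE entries outside [0, {PAE_MAX}] Å — corrupt or wrong units "
                f"(min {pae.min():.2f}, max {pae.max():.2f})"
            )
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.pae = pae
        return self

    @property
    def n_residues(self) -> int:
        return len(self.residue_chain)


@dataclass
class PairedModel:
    """A ComplexModel and its ConfidenceBundle with a fixed global indexing.

    ``chain_range[chain_id]`` gives the half-open global index range of that
    chain's residues within the PAE matrix.
    """

    model: ComplexModel
    bundle: ConfidenceBundle
    chain_range: dict[str, tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        offsets: dict[str, tuple[int, int]] = {}
        start = 0
        for ch in self.model.chains:
            offsets[ch.chain_id] = (start, start + len(ch))
            start += len(ch)
        self.chain_range = offsets

    @property
    def pae(self) -> np.ndarray:
        return self.bundle.pae

    def chain_slice(self, chain_id: str) -> slice:
        a, b = self.chain_range[chain_id]
        return slice(a, b)

    def plddt(self) -> np.ndarray:
        """Per-residue pLDDT; confidence-file values win over B-factors."""
        if self.bundle.plddt is not None:
            return np.asarray(self.bundle.plddt, dtype=float)
        return self.model.plddt_array()

    def global_residues(self) -> list[tuple[str, Residue]]:
        return [(c.chain_id, r) for c in self.model.chains for r in c.residues]


def attach(model: ComplexModel, bundle: ConfidenceBundle) -> PairedModel:
    """Pair a structure with its confidence bundle.

    The bundle's residue order is permuted to the model's chain order if it
    lists the same chains in a different order; the PAE matrix is permuted
    accordingly.  Raises ``ValueError`` when residue counts disagree.
    """
    model.validate()
    bundle.validate()
    if model.n_residues != bundle.n_residues:
        raise ValueError(
            f"residue count mismatch: model {model.model_id} has "
            f"{model.n_residues}, confidence bundle has {bundle.n_residues}"
        )
    model_order = [
        (c.chain_id, r.index) for c in model.chains for r in c.residues
    ]
    if all(cid == "?" for cid, _ in bundle.residue_chain):
        # dialects without a chain map: adopt the model's residue order
        bundle = replace(bundle, residue_chain=model_order)
    elif bundle.residue_chain != model_order:
        pos = {key: i for i, key in enumerate(bundle.residue_chain)}
        try:
            perm = np.array([pos[key] for key in model_order], dtype=int)
        except KeyError as e:
            raise ValueError(
                f"confidence bundle does not cover model residue {e.args[0]}"
            ) from None
        bundle = replace(
            bundle,
            pae=bundle.pae[np.ix_(perm, perm)],
            residue_chain=model_order,
            plddt=None if bundle.plddt is None else np.asarray(bundle.plddt)[perm],
        )
    return PairedModel(model=model, bundle=bundle)


def drop_nonstandard(residues: Iterable[tuple[str, str]]) -> list[str]:
    """Map nonstandard 3-letter codes to their parent residue; return the
    codes that had to be dropped (logged by the caller)."""
    dropped = []
    for _, name in residues:
        if name not in THREE_TO_ONE and name not in NONSTANDARD_PARENT:
            dropped.append(name)
    return dropped
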