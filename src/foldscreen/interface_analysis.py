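"""Interface residue detection, domain trimming, interface sharing, and
membrane-proximity flags.

Interfaces for residue-sharing analyses use a PISA-like heavy-atom 5 Å
contact definition; this is deliberately separate from the Cβ 8 Å contacts
pDockQ is defined over.  Trimming slices the existing PAE/pLDDT rather than
re-predicting, mirroring post-hoc trimming of models to their interacting
domains (e.g. the lipid-binding ORD domain of an ORP) before interface
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .model import Chain, ComplexModel, ConfidenceBundle, PairedModel, attach

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceSet",
    "DomainAnnotation",
    "MembraneFrame",
    "find_interface",
    "trim_to_domain",
    "shared_interface_fraction",
    "membrane_proximal_residues",
    "read_domain_annotations",
    "pymol_selection",
]


@dataclass
class InterfaceSet:
    """Interface residues of a chain pair: per-chain 1-based residue index
    sets plus the contact list with minimal heavy-atom distances."""

    chain_a: str
    chain_b: str
    residues_a: frozenset[int]
    residues_b: frozenset[int]
    contacts: list[tuple[int, int, float]]  # (res_a, res_b, min dist Å)


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str  # chain id or protein name resolved to a chain
    domain_name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid domain range {self.start}-{self.end} for "
                f"{self.protein_id}/{self.domain_name}"
            )


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane slab after external orientation (normal along z)."""

    z_upper: float
    z_lower: float

    def __post_init__(self) -> None:
        if not self.z_upper > self.z_lower:
            raise ValueError("z_upper must exceed z_lower")


def find_interface(model: ComplexModel, chain_a: str, chain_b: str,
                   config: ScoringConfig | None = None) -> InterfaceSet:
    """All residue contacts between two chains at the heavy-atom cutoff.

    A residue pair is a contact iff its minimal heavy-atom distance is
    ≤ ``config.interface_contact_cutoff`` (5.0 Å default).  Output ordering
    is deterministic: ascending (res_a, res_b).
    """
    config = config or ScoringConfig()
    cutoff = config.interface_contact_cutoff
    ca = model.chain(chain_a)
    cb = model.chain(chain_b)
    coords_b = [r.coords() for r in cb.residues]
    all_b = np.concatenate(coords_b)
    owner_b = np.repeat(np.arange(len(cb.residues)),
                        [len(c) for c in coords_b])
    contacts: list[tuple[int, int, float]] = []
    for i, res_a in enumerate(ca.residues):
        xyz = res_a.coords()
        d = np.linalg.norm(xyz[:, None, :] - all_b[None, :, :], axis=-1)
        dmin_atom = d.min(axis=0)
        # minimal distance per residue of chain B
        dmin = np.full(len(cb.residues), np.inf)
        np.minimum.at(dmin, owner_b, dmin_atom)
        for j in np.flatnonzero(dmin <= cutoff):
            contacts.append((res_a.index, cb.residues[j].index,
                             float(dmin[j])))
    contacts.sort()
    return InterfaceSet(
        chain_a=chain_a,
        chain_b=chain_b,
        residues_a=frozenset(a for a, _, _ in contacts),
        residues_b=frozenset(b for _, b, _ in contacts),
        contacts=contacts,
    )


def trim_to_domain(pair: PairedModel,
                   annotations: list[DomainAnnotation]) -> PairedModel:
    """Restrict annotated chains to their domain ranges.

    Residues outside any annotated range of their chain are removed; the
    PAE matrix and per-residue pLDDT are sliced to the survivors in
    original order.  Chains without an annotation are kept full length.
    Trimming with the same annotation twice is a no-op the second time
    (residues are re-indexed 1..n after the cut, so ranges must refer to
    the current numbering).
    """
    by_chain: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_chain.setdefault(ann.protein_id, []).append(ann)
    for cid, anns in by_chain.items():
        chain = pair.model.chain(cid)  # raises KeyError if missing
        for ann in anns:
            if ann.end > len(chain):
                raise ValueError(
                    f"domain {ann.domain_name} range {ann.start}-{ann.end} "
                    f"exceeds chain {cid} length {len(chain)}"
                )

    keep_global: list[int] = []
    new_chains: list[Chain] = []
    g = 0
    for chain in pair.model.chains:
        anns = by_chain.get(chain.chain_id)
        kept = []
        for r in chain.residues:
            keep = anns is None or any(
                a.start <= r.index <= a.end for a in anns
            )
            if keep:
                keep_global.append(g)
                kept.append(r)
            g += 1
        new_chains.append(Chain(
            chain_id=chain.chain_id,
            residues=[replace_index(r, i + 1) for i, r in enumerate(kept)],
        ))
    idx = np.asarray(keep_global, dtype=int)
    new_model = ComplexModel(
        model_id=pair.model.model_id,
        chains=[c for c in new_chains if len(c)],
        source_method=pair.model.source_method,
    )
    plddt = pair.bundle.plddt
    new_bundle = ConfidenceBundle(
        pae=pair.pae[np.ix_(idx, idx)],
        residue_chain=[(c.chain_id, r.index) for c in new_model.chains
                       for r in c.residues],
        ptm=pair.bundle.ptm,
        iptm=pair.bundle.iptm,
        chain_pair_iptm=pair.bundle.chain_pair_iptm,
        plddt=None if plddt is None else np.asarray(plddt)[idx],
    )
    return attach(new_model, new_bundle)


def replace_index(residue, new_index: int):
    return replace(residue, index=new_index)


def shared_interface_fraction(
    iface_1: InterfaceSet,
    iface_2: InterfaceSet,
    mapping: dict[tuple[str, int], tuple[str, int]] | None = None,
) -> tuple[float, float]:
    """Jaccard and directional overlap of two interface residue sets.

    ``mapping`` maps (chain, residue) of model 1 to model 2; identity when
    omitted.  Returns ``(jaccard, directional)`` where directional is
    |intersection| / |interface 1| — the "fraction of model 1's interface
    residues shared" reading.  Two empty interfaces define 1.0 (nothing to
    disagree on, warned).
    """
    set1 = {(iface_1.chain_a, r) for r in iface_1.residues_a} | {
        (iface_1.chain_b, r) for r in iface_1.residues_b
    }
    set2 = {(iface_2.chain_a, r) for r in iface_2.residues_a} | {
        (iface_2.chain_b, r) for r in iface_2.residues_b
    }
    if mapping is not None:
        set1 = {mapping[k] for k in set1 if k in mapping}
    if not set1 and not set2:
        logger.warning("both interfaces empty; shared fraction defined as 1.0")
        return 1.0, 1.0
    inter = len(set1 & set2)
    union = len(set1 | set2)
    jaccard = inter / union
    directional = inter / len(set1) if set1 else 0.0
    return jaccard, directional


def membrane_proximal_residues(
    model: ComplexModel,
    frame: MembraneFrame,
    config: ScoringConfig | None = None,
    both_leaflets: bool = False,
) -> set[tuple[str, int]]:
    """Residues with any atom within the cutoff of the membrane plane.

    The model must be externally oriented with the membrane normal along z.
    By default only the upper (cytosolic-side) leaflet plane is considered:
    a residue is flagged iff any atom satisfies |z − z_upper| ≤ cutoff
    (3.5 Å default).  ``both_leaflets`` additionally tests z_lower.
    """
    config = config or ScoringConfig()
    cutoff = config.membrane_proximity_cutoff
    flagged: set[tuple[str, int]] = set()
    for chain in model.chains:
        for res in chain.residues:
            z = res.coords()[:, 2]
            near = np.abs(z - frame.z_upper) <= cutoff
            if both_leaflets:
                near |= np.abs(z - frame.z_lower) <= cutoff
            if near.any():
                flagged.add((chain.chain_id, res.index))
    return flagged


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV with columns protein_id, domain, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DomainAnnotation(str(r.protein_id), str(r.domain),
                         int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def pymol_selection(name: str, residues: set[tuple[str, int]]) -> str:
    """PyMOL selection string for a flagged residue set."""
    by_chain: dict[str, list[int]] = {}
    for cid, idx in sorted(residues):
        by_chain.setdefault(cid, []).append(idx)
    parts = [
        f"(chain {cid} and resi {'+'.join(str(i) for i in idx)})"
        for cid, idx in sorted(by_chain.items())
    ]
    return f"select {name}, " + (" or ".join(parts) if parts else "none")
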