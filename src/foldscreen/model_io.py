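"""Readers and writers for predicted-complex structures, confidence JSON in
the two common dialects, score tables (TSV) and similarity networks (GraphML).

Structure parsing is delegated to gemmi; this module only converts to the
package's data model.  Two confidence-JSON dialects are understood:

* ``colabfold`` — AlphaFold2-Multimer / ColabFold style: residue-level
  ``pae`` (or ``predicted_aligned_error``), optional ``plddt``, ``ptm``,
  ``iptm``.  These files carry no chain map; the residue→chain assignment
  is taken from the structure at :func:`foldscreen.model.attach` time unless
  an explicit ``chain_ids``/``residue_ids`` pair is present.
* ``af3_server`` — AlphaFold3-server style: token-level ``pae`` with
  ``token_chain_ids`` and ``token_res_ids``.  Token PAE is reduced to
  residue level by keeping exactly one protein token per residue;
  non-protein tokens (ligands, ions) are discarded, identified via
  ``token_is_protein`` or ``token_res_names`` when present.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    Atom,
    Chain,
    ComplexModel,
    ConfidenceBundle,
    NONSTANDARD_PARENT,
    Residue,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "write_structure",
    "read_confidence",
    "write_score_table",
    "read_score_table",
    "write_network",
    "read_network",
]

SCORE_TABLE_COLUMNS = [
    "bait", "candidate", "method", "model_id", "chain_a", "chain_b",
    "weighted", "iptm", "ptm",
    "ipsae_ab", "ipsae_ba", "ipsae_max",
    "ipsae_d0chn_ab", "ipsae_d0chn_ba", "ipsae_d0chn_max",
    "ipsae_d0dom_ab", "ipsae_d0dom_ba", "ipsae_d0dom_max",
    "pdockq", "masked_iptm", "n_interface_residues",
    "weighted_label", "ipsae_label", "pdockq_label", "masked_iptm_label",
    "cluster_id", "localization_compatible", "membrane_plausible",
    "decision", "exclusion_reason",
]


# ---------------------------------------------------------------------------
# structures

def read_structure(path: str | Path, format: str = "auto") -> ComplexModel:
    """Read a predicted complex from mmCIF or PDB into a :class:`ComplexModel`.

    pLDDT is taken from the B-factor column (averaged over a residue's
    atoms), which is where AlphaFold deposits it.  Nonstandard residues are
    mapped to their parent amino acid when known, otherwise dropped with a
    warning.  Raises ``ValueError`` for unparsable files or files without
    protein residues.
    """
    path = Path(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse structure file {path}: {e}") from e
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")

    chains: list[Chain] = []
    dropped: set[str] = set()
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name
            if name not in THREE_TO_ONE:
                if name in NONSTANDARD_PARENT:
                    name = NONSTANDARD_PARENT[name]
                else:
                    dropped.add(gres.name)
                    continue
            atoms = [
                Atom(a.name, a.pos.x, a.pos.y, a.pos.z) for a in gres
            ]
            if not atoms:
                continue
            b = float(np.mean([a.b_iso for a in gres]))
            residues.append(
                Residue(index=len(residues) + 1, name=name, atoms=atoms,
                        plddt=min(max(b, 0.0), 100.0))
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if dropped:
        logger.warning("%s: dropped nonstandard residues %s", path,
                       sorted(dropped))
    if not chains:
        raise ValueError(f"{path}: no protein residues (empty model)")
    return ComplexModel(model_id=path.stem, chains=chains).validate()


def write_structure(model: ComplexModel, path: str | Path) -> None:
    """Write a ComplexModel as a PDB file; pLDDT goes to the B-factor column."""
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.element = gemmi.Element(atom.name[0])
                ga.b_iso = res.plddt
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# confidence JSON

_PAE_KEYS = ("pae", "predicted_aligned_error")


def _detect_dialect(data: dict) -> str:
    if "token_chain_ids" in data or "token_res_ids" in data:
        return "af3_server"
    return "colabfold"


def read_confidence(path: str | Path, dialect: str = "auto") -> ConfidenceBundle:
    """Read a confidence JSON file into a :class:`ConfidenceBundle`."""
    path = Path(path)
    data = json.loads(path.read_text())
    if isinstance(data, list):  # some ColabFold exports wrap in a list
        data = data[0]
    if dialect == "auto":
        dialect = _detect_dialect(data)
    pae_key = next((k for k in _PAE_KEYS if k in data), None)
    if pae_key is None:
        raise ValueError(
            f"{path}: no PAE found under keys {_PAE_KEYS} (dialect {dialect})"
        )
    pae = np.asarray(data[pae_key], dtype=float)

    if dialect == "af3_server":
        return _reduce_af3_tokens(path, data, pae)
    if dialect != "colabfold":
        raise ValueError(f"unknown confidence dialect {dialect!r}")

    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError(f"{path}: PAE matrix not square: shape {pae.shape}")
    n = pae.shape[0]
    if "chain_ids" in data and "residue_ids" in data:
        residue_chain = list(zip(data["chain_ids"],
                                 [int(i) for i in data["residue_ids"]]))
    else:
        residue_chain = None  # adopt the model's order at attach time
    plddt = None
    if "plddt" in data:
        plddt = np.asarray(data["plddt"], dtype=float)
        if plddt.shape != (n,):
            raise ValueError(f"{path}: plddt length {plddt.shape} != PAE dim {n}")
    return ConfidenceBundle(
        pae=pae,
        residue_chain=residue_chain if residue_chain is not None
        else [("?", i + 1) for i in range(n)],
        ptm=data.get("ptm"),
        iptm=data.get("iptm"),
        plddt=plddt,
    ).validate()


def _reduce_af3_tokens(path: Path, data: dict, pae: np.ndarray) -> ConfidenceBundle:
    """Reduce AF3-server token-level PAE to residue level.

    Keeps exactly the first protein token of each (chain, residue); ligand
    and ion tokens are dropped.
    """
    chain_ids = data.get("token_chain_ids")
    res_ids = data.get("token_res_ids")
    if chain_ids is None or res_ids is None:
        raise ValueError(
            f"{path}: af3_server dialect needs token_chain_ids and token_res_ids"
        )
    n_tok = len(chain_ids)
    if pae.shape != (n_tok, n_tok):
        raise ValueError(
            f"{path}: token PAE shape {pae.shape} inconsistent with "
            f"{n_tok} tokens"
        )
    if "token_is_protein" in data:
        is_protein = [bool(b) for b in data["token_is_protein"]]
    elif "token_res_names" in data:
        is_protein = [
            name in THREE_TO_ONE or name in NONSTANDARD_PARENT
            for name in data["token_res_names"]
        ]
    else:
        is_protein = [True] * n_tok

    keep: list[int] = []
    seen: set[tuple[str, int]] = set()
    residue_chain: list[tuple[str, int]] = []
    for t in range(n_tok):
        if not is_protein[t]:
            continue
        key = (str(chain_ids[t]), int(res_ids[t]))
        if key in seen:
            continue
        seen.add(key)
        keep.append(t)
        residue_chain.append(key)
    if not keep:
        raise ValueError(f"{path}: no protein tokens after reduction")
    idx = np.asarray(keep, dtype=int)
    reduced = pae[np.ix_(idx, idx)]

    cp_iptm = None
    if "chain_pair_iptm" in data and "chain_ids_order" in data:
        order = [str(c) for c in data["chain_ids_order"]]
        m = np.asarray(data["chain_pair_iptm"], dtype=float)
        cp_iptm = {
            (order[i], order[j]): float(m[i, j])
            for i in range(len(order)) for j in range(len(order))
        }
    return ConfidenceBundle(
        pae=reduced,
        residue_chain=residue_chain,
        ptm=data.get("ptm"),
        iptm=data.get("iptm"),
        chain_pair_iptm=cp_iptm,
    ).validate()


# ---------------------------------------------------------------------------
# score tables

def write_score_table(records, path: str | Path) -> None:
    """Write screen records as a UTF-8 TSV with the documented column order."""
    df = records.to_dataframe() if hasattr(records, "to_dataframe") \
        else records.copy()
    if len(df) == 0:
        raise ValueError("refusing to write an empty score table")
    for col in SCORE_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[SCORE_TABLE_COLUMNS]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# networks

def write_network(net, path: str | Path) -> None:
    """Write an interaction network as GraphML.

    Nodes carry ``weighted`` score and ``method``; edges carry
    ``interface_lddt``.  Accepts an ``InteractionNetwork`` (duck-typed via
    ``.graph``) or a bare networkx Graph.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    nx.write_graphml(graph, str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
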