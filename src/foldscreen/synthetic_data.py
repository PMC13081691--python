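"""Desk-scale synthetic predicted-complex fixtures.

Generates idealized two- to four-chain models with the statistical
structure the triage pipeline assumes: α-helical chains with backbone+CB
atoms, a structured PAE matrix (low within chains, a tunable
``pae_inter_base`` between chains), per-residue pLDDT, and pTM/ipTM
summaries tied to interface quality by a documented monotone map.  The
``pae_inter_base`` dial separates true-like complexes (confident, low
interchain PAE) from false-like ones (interchain PAE above any sensible
cutoff), which is all the downstream metrics respond to.

Chains are idealized helices, not real folds: every scored quantity is
distance- or PAE-based, so realistic side chains are unnecessary.  The
ipTM map ``iptm = clip(1.1·exp(−pae_inter_base/8), 0, 0.95)`` (plus small
seeded noise) is a fixture convention, not a physical relation.  All output
is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Atom,
    Chain,
    ComplexModel,
    ConfidenceBundle,
    ONE_TO_THREE,
    Residue,
)
from .model_io import write_structure

__all__ = [
    "SyntheticSpec",
    "make_helix_chain",
    "make_dimer",
    "perturb_pose",
    "make_pose_groups",
    "make_screen_fixture",
]

HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Å, Cα radius

# 20-letter alphabet used to give synthetic chains non-trivial sequences
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dimer (or multimer) fixture."""

    seed: int = 0
    chain_lengths: tuple[int, ...] = (30, 30)
    interface_gap: float = 4.0      # Å closest approach between chains
    pae_intra_base: float = 2.0     # Å
    pae_inter_base: float = 4.0     # Å; the true/false dial
    pae_noise_sd: float = 0.3       # Å
    plddt_base: float = 90.0
    plddt_noise_sd: float = 2.0
    label: str = "true-like"        # or "false-like"
    model_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.interface_gap < 0:
            raise ValueError("interface_gap must be non-negative")
        for name in ("pae_intra_base", "pae_inter_base", "pae_noise_sd",
                     "plddt_base", "plddt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _helix_point(t: float, radius: float = HELIX_RADIUS) -> np.ndarray:
    theta = np.deg2rad(HELIX_TWIST) * t
    return np.array([radius * np.cos(theta), radius * np.sin(theta),
                     HELIX_RISE * t])


def make_helix_chain(chain_id: str, length: int, rng: np.random.Generator,
                     plddt: np.ndarray | None = None) -> Chain:
    """Idealized α-helix with N/CA/C/O/CB atoms and a random sequence."""
    residues = []
    seq_idx = rng.integers(0, len(_AA), size=length)
    for i in range(length):
        ca = _helix_point(i)
        n = _helix_point(i - 0.35, radius=1.8)
        c = _helix_point(i + 0.35, radius=1.9)
        o = c + np.array([0.0, 0.0, 1.23])
        cb = ca * np.array([1.65, 1.65, 1.0])  # radially outward from axis
        aa1 = _AA[seq_idx[i]]
        atoms = [Atom("N", *n), Atom("CA", *ca), Atom("C", *c),
                 Atom("O", *o)]
        if aa1 != "G":
            atoms.append(Atom("CB", *cb))
        residues.append(Residue(
            index=i + 1,
            name=ONE_TO_THREE[aa1],
            atoms=atoms,
            plddt=float(plddt[i]) if plddt is not None else 90.0,
        ))
    return Chain(chain_id=chain_id, residues=residues)


def _transform_chain(chain: Chain, rotation: np.ndarray,
                     translation: np.ndarray) -> Chain:
    new_res = []
    for r in chain.residues:
        atoms = [
            Atom(a.name, *(rotation @ np.array([a.x, a.y, a.z]) + translation))
            for a in r.atoms
        ]
        new_res.append(Residue(index=r.index, name=r.name, atoms=atoms,
                               plddt=r.plddt))
    return Chain(chain_id=chain.chain_id, residues=new_res)


def _min_distance(chain_a: Chain, chain_b: Chain) -> float:
    xa = np.concatenate([r.coords() for r in chain_a.residues])
    xb = np.concatenate([r.coords() for r in chain_b.residues])
    return float(np.linalg.norm(xa[:, None] - xb[None, :], axis=-1).min())


def iptm_from_pae(pae_inter_base: float) -> float:
    """Fixture convention tying summary ipTM to interface PAE (monotone,
    non-physical)."""
    return float(np.clip(1.1 * np.exp(-pae_inter_base / 8.0), 0.0, 0.95))


def make_dimer(spec: SyntheticSpec) -> tuple[ComplexModel, ConfidenceBundle]:
    """Build a synthetic complex and its matching confidence bundle.

    Chain A sits on the origin; each further chain is a parallel helix
    placed along +x so its closest heavy-atom approach to chain A equals
    ``interface_gap``; successive chains are stacked with the same gap.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = tuple(int(n) for n in spec.chain_lengths)
    n_total = sum(lengths)
    chain_ids = [chr(ord("A") + k) for k in range(len(lengths))]

    plddt = np.clip(
        spec.plddt_base + rng.normal(0.0, spec.plddt_noise_sd, n_total),
        0.0, 100.0,
    )
    chains: list[Chain] = []
    offset = 0
    for k, (cid, ln) in enumerate(zip(chain_ids, lengths)):
        chain = make_helix_chain(cid, ln, rng,
                                 plddt=plddt[offset:offset + ln])
        if k > 0:
            # parallel helix along +x from the previous chain, shifted so
            # the closest heavy-atom approach equals interface_gap (the
            # min-distance vector between parallel helices is ~along x, so
            # two correction steps converge)
            ref = chains[k - 1]
            x0 = max(a.x for r in ref.residues for a in r.atoms) + 10.0
            for _ in range(3):
                probe = _transform_chain(chain, np.eye(3),
                                         np.array([x0, 0.0, 0.0]))
                x0 += spec.interface_gap - _min_distance(ref, probe)
            chain = _transform_chain(chain, np.eye(3),
                                     np.array([x0, 0.0, 0.0]))
        chains.append(chain)
    model = ComplexModel(model_id=spec.model_id, chains=chains,
                         source_method="synthetic").validate()

    # structured PAE: low within chains, pae_inter_base between chains,
    # independent noise on (i, j) and (j, i)
    pae = np.full((n_total, n_total), spec.pae_inter_base)
    start = 0
    for ln in lengths:
        pae[start:start + ln, start:start + ln] = spec.pae_intra_base
        start += ln
    pae = pae + rng.normal(0.0, spec.pae_noise_sd, (n_total, n_total))
    np.fill_diagonal(pae, 0.0)
    pae = np.clip(pae, 0.0, 35.0)

    iptm = float(np.clip(
        iptm_from_pae(spec.pae_inter_base) + rng.normal(0.0, 0.005),
        0.0, 1.0))
    ptm = float(np.clip(0.85 * iptm + 0.10, 0.0, 1.0))
    bundle = ConfidenceBundle(
        pae=pae,
        residue_chain=[(c.chain_id, r.index) for c in model.chains
                       for r in c.residues],
        ptm=ptm,
        iptm=iptm,
        plddt=plddt,
    ).validate()
    return model, bundle


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def perturb_pose(model: ComplexModel,
                 magnitude: float | tuple[float, float],
                 seed: int = 0,
                 chain_id: str | None = None) -> ComplexModel:
    """Apply a random rigid transform of given magnitude to one chain.

    ``magnitude`` is a translation norm in Å, or a ``(Å, degrees)`` pair
    adding a rotation about the chain centroid.  Magnitude 0 is the
    identity.  The perturbed chain defaults to the last one.
    """
    trans_mag, rot_deg = (magnitude if isinstance(magnitude, tuple)
                          else (float(magnitude), 0.0))
    rng = np.random.default_rng(seed)
    cid = chain_id or model.chains[-1].chain_id
    new_chains = []
    for chain in model.chains:
        if chain.chain_id != cid:
            new_chains.append(chain)
            continue
        xyz = np.concatenate([r.coords() for r in chain.residues])
        centroid = xyz.mean(axis=0)
        rot = (_random_rotation(rng, rot_deg) if rot_deg else np.eye(3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = centroid - rot @ centroid + trans_mag * direction
        new_chains.append(_transform_chain(chain, rot, shift))
    return ComplexModel(model_id=model.model_id, chains=new_chains,
                        source_method=model.source_method)


def make_pose_groups(n_groups: int = 3, n_per_group: int = 5,
                     seed: int = 0, chain_length: int = 25,
                     within_magnitude: tuple[float, float] = (0.25, 1.0),
                     ) -> list[tuple[str, int, ComplexModel]]:
    """Families of dimers with distinct docking poses between groups and
    sub-Å pose jitter within groups.

    Group g docks chain B against a different face of chain A (rotated by
    g·(360/n_groups)° about the helix axis), displacing it by well over
    10 Å relative to other groups; within a group each replicate applies a
    small random rigid perturbation.  Returns (model_id, group, model).
    """
    rng = np.random.default_rng(seed)
    out = []
    base_spec = SyntheticSpec(seed=seed, chain_lengths=(chain_length,
                                                        chain_length))
    base_model, _ = make_dimer(base_spec)
    for g in range(n_groups):
        angle = np.deg2rad(g * 360.0 / n_groups)
        rot_z = np.array([
            [np.cos(angle), -np.sin(angle), 0.0],
            [np.sin(angle), np.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ])
        chains = [base_model.chains[0],
                  _transform_chain(base_model.chains[1], rot_z,
                                   np.zeros(3))]
        group_model = ComplexModel(
            model_id=f"group{g}", chains=chains, source_method="synthetic")
        for r in range(n_per_group):
            m = perturb_pose(group_model, within_magnitude,
                             seed=int(rng.integers(0, 2**31 - 1)))
            m.model_id = f"g{g}_r{r}"
            out.append((m.model_id, g, m))
    return out


def make_screen_fixture(n_pairs: int, frac_true: float, seed: int,
                        outdir: str | Path,
                        chain_length: int = 30) -> Path:
    """Write a labeled synthetic screen: structures, ColabFold-dialect
    confidence JSONs, a manifest TSV and a ground-truth label TSV.

    True-like pairs draw ``pae_inter_base`` ≤ 6 Å (giving summary ipTM
    above 0.6 through the fixture's monotone map) and a docked geometry;
    false-like pairs draw interchain PAE of 20 Å or more (ipTM below 0.3)
    and a wider interface gap.  Returns the manifest path.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be ≥ 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_true = round(n_pairs * frac_true)
    rows, labels = [], []
    for k in range(n_pairs):
        true_like = k < n_true
        if true_like:
            inter = float(rng.uniform(2.0, 4.5))
            gap, label = 4.0, "true-like"
        else:
            inter = float(rng.uniform(20.0, 30.0))
            gap, label = 12.0, "false-like"
        spec = SyntheticSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            chain_lengths=(chain_length, chain_length),
            interface_gap=gap,
            pae_inter_base=inter,
            label=label,
            model_id=f"pair{k:03d}",
        )
        model, bundle = make_dimer(spec)
        pdb_path = outdir / f"pair{k:03d}.pdb"
        json_path = outdir / f"pair{k:03d}_scores.json"
        write_structure(model, pdb_path)
        json_path.write_text(json.dumps({
            "pae": bundle.pae.round(4).tolist(),
            "plddt": np.asarray(bundle.plddt).round(2).tolist(),
            "ptm": bundle.ptm,
            "iptm": bundle.iptm,
        }))
        bait, cand = f"bait{k:03d}", f"cand{k:03d}"
        rows.append({
            "model_path": pdb_path.name,
            "confidence_path": json_path.name,
            "bait": bait, "candidate": cand, "method": "af2m",
        })
        labels.append({"bait": bait, "candidate": cand, "label": label})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    pd.DataFrame(labels).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return manifest
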