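"""Interface confidence metrics for a chain pair of a predicted complex.

Implements the metric family used to triage candidate protein–protein
interactions from predicted models:

* the weighted ranking score ``0.8·ipTM + 0.2·pTM``;
* ipSAE and its ``d0chn``/``d0dom`` variants — interface scores computed
  solely from interchain residue pairs whose predicted aligned error (PAE)
  lies below a cutoff, using the TM-score kernel ``1/(1+(PAE/d0)²)``.  The
  variants differ in the residue count ``n`` fed to the TM normalisation
  distance ``d0(n)``: the per-residue count of sub-cutoff partners
  (``ipsae``), the summed chain lengths (``d0chn``), or the number of
  residues participating in any sub-cutoff interchain pair (``d0dom``);
* pDockQ — a sigmoid of (mean interface pLDDT) × ln(number of Cβ–Cβ
  contacts);
* a masked interface pTM: an ipTM-style score restricted to residues in
  coordinate contact across the interface.  This is a coordinate-contact
  approximation of the distogram-weighted actifpTM score (distograms are
  not available outside the predictor) and is labelled
  ``masked_iptm(actifpTM-approx)`` in outputs.

All asymmetric scores report both directions and their max; the max is the
headline value.  PAE comparisons use strict ``<`` (ties at the cutoff are
excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScoringConfig
from .model import PairedModel

__all__ = [
    "ChainPairScores",
    "weighted_score",
    "d0_of",
    "ipsae",
    "pdockq",
    "masked_interface_ptm",
    "classify_scores",
    "score_chain_pair",
]

# pDockQ sigmoid constants (single-interface fit)
_PDOCKQ_L = 0.724
_PDOCKQ_K = 0.052
_PDOCKQ_X0 = 152.611
_PDOCKQ_B = 0.018

D0_FLOOR = 1.0  # Å; raw d0 is negative/complex for small n


@dataclass
class ChainPairScores:
    """All interface confidence metrics for one ordered chain pair."""

    chain_a: str
    chain_b: str
    weighted: float | None
    ipsae: tuple[float, float, float]
    ipsae_d0chn: tuple[float, float, float]
    ipsae_d0dom: tuple[float, float, float]
    pdockq: float
    masked_iptm: float
    n_interface_residues: int
    labels: dict[str, str] = field(default_factory=dict)


def weighted_score(iptm: float, ptm: float,
                   weights: tuple[float, float] = (0.8, 0.2)) -> float:
    """Weighted ipTM+pTM ranking score, by default 0.8·ipTM + 0.2·pTM."""
    for name, v in (("iptm", iptm), ("ptm", ptm)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return weights[0] * iptm + weights[1] * ptm


def d0_of(n: int | np.ndarray) -> float | np.ndarray:
    """TM-score normalisation distance d0(n) = 1.24·(n−15)^⅓ − 1.8, clamped
    below at 1.0 Å.  Monotone non-decreasing in n."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError(f"d0 undefined for n < 1 (got {n})")
    raw = 1.24 * np.cbrt(np.maximum(n_arr - 15.0, 0.0)) - 1.8
    out = np.maximum(raw, D0_FLOOR)
    return float(out) if np.isscalar(n) or n_arr.ndim == 0 else out


def _tm_kernel(pae: np.ndarray, d0: float | np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + (pae / d0) ** 2)


def _ipsae_direction(block: np.ndarray, n_chn: int, variant: str,
                     pae_cutoff: float) -> float:
    """One direction of ipSAE over a PAE block (rows = aligned-on chain)."""
    below = block < pae_cutoff
    if not below.any():
        return 0.0
    if variant == "ipsae":
        # per-residue d0 from that residue's own sub-cutoff partner count
        counts = below.sum(axis=1)
        rows = np.flatnonzero(counts)
        d0_rows = d0_of(counts[rows])
        scores = [
            _tm_kernel(block[i, below[i]], d0_rows[k]).mean()
            for k, i in enumerate(rows)
        ]
    elif variant == "d0chn":
        d0 = d0_of(n_chn)
        scores = [
            _tm_kernel(block[i, below[i]], d0).mean()
            for i in np.flatnonzero(below.any(axis=1))
        ]
    elif variant == "d0dom":
        n_dom = int(below.any(axis=1).sum() + below.any(axis=0).sum())
        d0 = d0_of(n_dom)
        scores = [
            _tm_kernel(block[i, below[i]], d0).mean()
            for i in np.flatnonzero(below.any(axis=1))
        ]
    else:
        raise ValueError(f"unknown ipSAE variant {variant!r}")
    return float(max(scores))


def ipsae(pair: PairedModel, chain_a: str, chain_b: str,
          config: ScoringConfig | None = None
          ) -> dict[str, tuple[float, float, float]]:
    """All three ipSAE variants for a chain pair.

    Returns ``{variant: (a_to_b, b_to_a, max)}`` for variants ``ipsae``,
    ``d0chn`` and ``d0dom``.  Direction A→B aligns on residues of A and
    scores their sub-cutoff partners in B; a direction with no interchain
    PAE below the cutoff scores exactly 0.0.
    """
    config = config or ScoringConfig()
    sa, sb = pair.chain_slice(chain_a), pair.chain_slice(chain_b)
    la, lb = sa.stop - sa.start, sb.stop - sb.start
    block_ab = pair.pae[sa, sb]
    block_ba = pair.pae[sb, sa]
    out = {}
    for variant in ("ipsae", "d0chn", "d0dom"):
        ab = _ipsae_direction(block_ab, la + lb, variant, config.pae_cutoff)
        ba = _ipsae_direction(block_ba, la + lb, variant, config.pae_cutoff)
        out[variant] = (ab, ba, max(ab, ba))
    return out


def pdockq(pair: PairedModel, chain_a: str, chain_b: str,
           config: ScoringConfig | None = None) -> float:
    """pDockQ for a chain pair.

    Contacts are interchain residue pairs with Cβ–Cβ distance (Cα for
    glycine) ≤ 8 Å; x = mean pLDDT over contact residues × ln(contact
    count); the score is 0.724/(1+exp(−0.052·(x−152.611))) + 0.018, with
    floor 0.018 at zero contacts.
    """
    config = config or ScoringConfig()
    ca = pair.model.chain(chain_a)
    cb = pair.model.chain(chain_b)
    xyz_a = np.array([r.cb_coord() for r in ca.residues], dtype=float)
    xyz_b = np.array([r.cb_coord() for r in cb.residues], dtype=float)
    if np.any(~np.isfinite(xyz_a)) or np.any(~np.isfinite(xyz_b)):
        raise ValueError("missing Cβ/Cα coordinates for pDockQ")
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    contact = d <= config.cb_contact_cutoff
    n_contacts = int(contact.sum())
    if n_contacts == 0:
        return _PDOCKQ_B
    plddt = pair.plddt()
    ia = np.flatnonzero(contact.any(axis=1)) + pair.chain_range[chain_a][0]
    ib = np.flatnonzero(contact.any(axis=0)) + pair.chain_range[chain_b][0]
    mean_plddt = float(plddt[np.concatenate([ia, ib])].mean())
    x = mean_plddt * np.log(n_contacts)
    return float(_PDOCKQ_L / (1.0 + np.exp(-_PDOCKQ_K * (x - _PDOCKQ_X0)))
                 + _PDOCKQ_B)


def pdockq_from_x(x: float) -> float:
    """The pDockQ sigmoid as a function of x = mean interface pLDDT × ln n."""
    return float(_PDOCKQ_L / (1.0 + np.exp(-_PDOCKQ_K * (x - _PDOCKQ_X0)))
                 + _PDOCKQ_B)


def interface_residue_mask(pair: PairedModel, chain_a: str, chain_b: str,
                           cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the two chains' residues marking those with any
    interchain heavy-atom distance ≤ cutoff."""
    res_a = pair.model.chain(chain_a).residues
    res_b = pair.model.chain(chain_b).residues
    coords_a = [r.coords() for r in res_a]
    coords_b = [r.coords() for r in res_b]
    all_b = np.concatenate(coords_b)
    owner_b = np.repeat(np.arange(len(res_b)), [len(c) for c in coords_b])
    mask_a = np.zeros(len(res_a), dtype=bool)
    mask_b = np.zeros(len(res_b), dtype=bool)
    for i, ca in enumerate(coords_a):
        d = np.linalg.norm(ca[:, None, :] - all_b[None, :, :], axis=-1)
        hit = (d <= cutoff).any(axis=0)
        if hit.any():
            mask_a[i] = True
            mask_b[np.unique(owner_b[hit])] = True
    return mask_a, mask_b


def masked_interface_ptm(pair: PairedModel, chain_a: str, chain_b: str,
                         config: ScoringConfig | None = None) -> float:
    """ipTM-style score restricted to residues in coordinate contact.

    The interface set I holds residues of either chain with any interchain
    heavy-atom distance ≤ the Cβ contact cutoff; the score is the max over
    directions of the max over i∈I of the mean TM kernel over interchain
    partners j∈I, with d0 = d0(|I|).  Returns 0.0 when I is empty.
    """
    config = config or ScoringConfig()
    mask_a, mask_b = interface_residue_mask(pair, chain_a, chain_b,
                                            config.cb_contact_cutoff)
    n_iface = int(mask_a.sum() + mask_b.sum())
    if n_iface == 0:
        return 0.0
    d0 = d0_of(n_iface)
    sa, sb = pair.chain_slice(chain_a), pair.chain_slice(chain_b)
    sub = pair.pae[sa, sb][np.ix_(mask_a, mask_b)]
    ab = float(_tm_kernel(sub, d0).mean(axis=1).max())
    sub_t = pair.pae[sb, sa][np.ix_(mask_b, mask_a)]
    ba = float(_tm_kernel(sub_t, d0).mean(axis=1).max())
    return max(ab, ba)


def classify_scores(scores: ChainPairScores,
                    config: ScoringConfig | None = None) -> dict[str, str]:
    """Band labels for each metric.

    weighted: >0.80 high, (0.60, 0.80] intermediate, (0.40, 0.60]
    permissive-pass, ≤0.40 fail.  ipSAE (d0dom max): <0.20 false-like,
    >0.40 true-like, else indeterminate.  pDockQ: <0.23 fail, [0.23, 0.49)
    acceptable, [0.49, 0.80) medium, ≥0.80 high.  masked ipTM: >0.70
    reliable, [0.60, 0.70] intermediate, <0.60 low.
    """
    config = config or ScoringConfig()
    labels: dict[str, str] = {}

    w = scores.weighted
    lo, hi = config.weighted_bands
    if w is None:
        labels["weighted"] = "missing"
    elif w > hi:
        labels["weighted"] = "high"
    elif w > lo:
        labels["weighted"] = "intermediate"
    elif w > config.weighted_permissive:
        labels["weighted"] = "permissive-pass"
    else:
        labels["weighted"] = "fail"

    s = scores.ipsae_d0dom[2]
    if s < config.ipsae_false_max:
        labels["ipsae"] = "false-like"
    elif s > config.ipsae_true_min:
        labels["ipsae"] = "true-like"
    else:
        labels["ipsae"] = "indeterminate"

    p = scores.pdockq
    acc, med, high = config.pdockq_bands
    if p < acc:
        labels["pdockq"] = "fail"
    elif p < med:
        labels["pdockq"] = "acceptable"
    elif p < high:
        labels["pdockq"] = "medium"
    else:
        labels["pdockq"] = "high"

    m = scores.masked_iptm
    lo_m, hi_m = config.actifptm_bands[:2]
    if m > hi_m:
        labels["masked_iptm"] = "reliable"
    elif m >= lo_m:
        labels["masked_iptm"] = "intermediate"
    else:
        labels["masked_iptm"] = "low"
    return labels


def score_chain_pair(pair: PairedModel, chain_a: str, chain_b: str,
                     config: ScoringConfig | None = None) -> ChainPairScores:
    """Compute the full metric family for one chain pair and label it."""
    config = config or ScoringConfig()
    b = pair.bundle
    weighted = None
    if b.iptm is not None and b.ptm is not None:
        weighted = weighted_score(b.iptm, b.ptm, config.weighted_weights)
    variants = ipsae(pair, chain_a, chain_b, config)
    mask_a, mask_b = interface_residue_mask(pair, chain_a, chain_b,
                                            config.cb_contact_cutoff)
    scores = ChainPairScores(
        chain_a=chain_a,
        chain_b=chain_b,
        weighted=weighted,
        ipsae=variants["ipsae"],
        ipsae_d0chn=variants["d0chn"],
        ipsae_d0dom=variants["d0dom"],
        pdockq=pdockq(pair, chain_a, chain_b, config),
        masked_iptm=masked_interface_ptm(pair, chain_a, chain_b, config),
        n_interface_residues=int(mask_a.sum() + mask_b.sum()),
    )
    scores.labels = classify_scores(scores, config)
    return scores
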