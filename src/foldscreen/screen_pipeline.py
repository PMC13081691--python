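"""All-against-all triage of candidate protein–protein interactions.

``run_screen`` scores every bait–candidate model in a manifest with the
full confidence-metric family and applies the screen's filters in
documented order: the permissive weighted ipTM+pTM filter (> 0.40) first,
then the pDockQ accept cutoff (≥ 0.23).  ipSAE banding is recorded but is
never an exclusion criterion on its own.  A record falling at a filter
carries the first failing filter as its exclusion reason; an unreadable
row is logged and recorded as failed without aborting the screen.

``consensus_report`` combines the screen table with an interface-similarity
network: a pair is consensus-supported when retained models of that pair
from at least two distinct prediction methods fall in the same interface
cluster.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ScoringConfig
from .confidence_scores import ChainPairScores, score_chain_pair
from .interface_analysis import (
    DomainAnnotation,
    MembraneFrame,
    find_interface,
    membrane_proximal_residues,
)
from .interface_similarity import InteractionNetwork
from .model import attach
from .model_io import SCORE_TABLE_COLUMNS, read_confidence, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenRecord",
    "ScreenTable",
    "run_screen",
    "consensus_report",
    "localization_compatibility",
    "membrane_plausibility",
    "read_localization_table",
]

REASON_WEIGHTED = "weighted ≤ 0.40"
REASON_PDOCKQ = "pDockQ < 0.23"

# Compartments facing the cytosol: any two of these can in principle meet.
_CYTOSOL_ADJACENT = {
    "cytosol", "cytoplasm", "er", "er membrane", "golgi", "golgi membrane",
    "plasma membrane", "mitochondrial outer membrane", "endosome",
    "lipid droplet",
}
# Topologically isolated from the cytosol.
_LUMINAL = {"er lumen", "golgi lumen", "mitochondrial matrix",
            "extracellular", "lysosome lumen"}


@dataclass
class ScreenRecord:
    bait: str
    candidate: str
    method: str
    model_id: str
    scores: ChainPairScores | None
    cluster_id: str | None = None
    localization_compatible: str = "unknown"  # yes | no | unknown
    membrane_plausible: str = "unknown"
    decision: str = "indeterminate"  # retain | exclude | indeterminate
    exclusion_reason: str = ""


@dataclass
class ScreenTable:
    records: list[ScreenRecord]
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            s = r.scores
            row = {
                "bait": r.bait, "candidate": r.candidate,
                "method": r.method, "model_id": r.model_id,
                "cluster_id": r.cluster_id,
                "localization_compatible": r.localization_compatible,
                "membrane_plausible": r.membrane_plausible,
                "decision": r.decision,
                "exclusion_reason": r.exclusion_reason,
            }
            if s is not None:
                row.update({
                    "chain_a": s.chain_a, "chain_b": s.chain_b,
                    "weighted": s.weighted,
                    "ipsae_ab": s.ipsae[0], "ipsae_ba": s.ipsae[1],
                    "ipsae_max": s.ipsae[2],
                    "ipsae_d0chn_ab": s.ipsae_d0chn[0],
                    "ipsae_d0chn_ba": s.ipsae_d0chn[1],
                    "ipsae_d0chn_max": s.ipsae_d0chn[2],
                    "ipsae_d0dom_ab": s.ipsae_d0dom[0],
                    "ipsae_d0dom_ba": s.ipsae_d0dom[1],
                    "ipsae_d0dom_max": s.ipsae_d0dom[2],
                    "pdockq": s.pdockq,
                    "masked_iptm": s.masked_iptm,
                    "n_interface_residues": s.n_interface_residues,
                    "weighted_label": s.labels.get("weighted"),
                    "ipsae_label": s.labels.get("ipsae"),
                    "pdockq_label": s.labels.get("pdockq"),
                    "masked_iptm_label": s.labels.get("masked_iptm"),
                })
            rows.append(row)
        df = pd.DataFrame(rows)
        for col in SCORE_TABLE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        return df[SCORE_TABLE_COLUMNS]

    def retained(self) -> list[ScreenRecord]:
        return [r for r in self.records if r.decision == "retain"]


def _decide(scores: ChainPairScores, config: ScoringConfig) -> tuple[str, str]:
    """Apply the screen filters in documented order; the two exclusion
    filters commute for the retain set, the reason reflects the first."""
    if scores.weighted is None or scores.weighted <= config.weighted_permissive:
        return "exclude", REASON_WEIGHTED
    if scores.pdockq < config.pdockq_bands[0]:
        return "exclude", REASON_PDOCKQ
    return "retain", ""


def run_screen(manifest: str | Path | pd.DataFrame,
               config: ScoringConfig | None = None,
               base_dir: str | Path | None = None,
               localization: dict[str, set[str]] | None = None) -> ScreenTable:
    """Score and triage every model in a screen manifest.

    ``manifest`` is a TSV (or DataFrame) with columns model_path,
    confidence_path, bait, candidate, method; relative paths resolve
    against the manifest's directory (or ``base_dir``).
    """
    config = config or ScoringConfig()
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        df = pd.read_csv(mpath, sep="\t")
        base = Path(base_dir) if base_dir else mpath.parent
    else:
        df = manifest
        base = Path(base_dir) if base_dir else Path(".")
    required = {"model_path", "confidence_path", "bait", "candidate", "method"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")

    records: list[ScreenRecord] = []
    for row in df.itertuples():
        model_id = Path(str(row.model_path)).stem
        try:
            model = read_structure(base / str(row.model_path))
            bundle = read_confidence(base / str(row.confidence_path))
            pair = attach(model, bundle)
            if len(model.chains) < 2:
                raise ValueError(f"{model_id}: needs ≥2 chains for screening")
            ca, cb = model.chain_ids[:2]
            scores = score_chain_pair(pair, ca, cb, config)
        except Exception as e:  # partial-failure contract
            logger.warning("screen row %s failed: %s", model_id, e)
            records.append(ScreenRecord(
                bait=str(row.bait), candidate=str(row.candidate),
                method=str(row.method), model_id=model_id, scores=None,
                decision="indeterminate",
                exclusion_reason=f"failed: {e}",
            ))
            continue
        decision, reason = _decide(scores, config)
        rec = ScreenRecord(
            bait=str(row.bait), candidate=str(row.candidate),
            method=str(row.method), model_id=model_id, scores=scores,
            decision=decision, exclusion_reason=reason,
        )
        if localization is not None:
            rec.localization_compatible = localization_compatibility(
                (rec.bait, rec.candidate), localization)
        records.append(rec)
    return ScreenTable(
        records=records,
        provenance={
            "config": config.to_dict(),
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
            "n_rows": len(records),
        },
    )


def consensus_report(table: ScreenTable,
                     net: InteractionNetwork) -> pd.DataFrame:
    """Rank pairs by cross-method consensus within interface clusters.

    For each (bait, candidate) pair the retained models are looked up in
    the network's clusters; the pair's support tier is the largest number
    of distinct methods whose retained models share one cluster (models
    missing from the network count as their own singleton).
    """
    cluster_of: dict[str, int] = {}
    for i, members in enumerate(net.clusters):
        for m in members:
            cluster_of[m] = i
    pairs: dict[tuple[str, str], list[ScreenRecord]] = {}
    for rec in table.retained():
        pairs.setdefault((rec.bait, rec.candidate), []).append(rec)

    rows = []
    for (bait, cand), recs in sorted(pairs.items()):
        by_cluster: dict[int | str, set[str]] = {}
        for rec in recs:
            cl = cluster_of.get(rec.model_id, f"unclustered:{rec.model_id}")
            by_cluster.setdefault(cl, set()).add(rec.method)
        support = max(len(methods) for methods in by_cluster.values())
        best = max((r.scores.weighted or 0.0) for r in recs
                   if r.scores is not None)
        rows.append({
            "bait": bait, "candidate": cand,
            "n_models_retained": len(recs),
            "methods": ",".join(sorted({r.method for r in recs})),
            "consensus_methods": support,
            "consensus_supported": support >= 2,
            "best_weighted": best,
        })
    return pd.DataFrame(rows).sort_values(
        ["consensus_methods", "best_weighted"], ascending=False
    ).reset_index(drop=True) if rows else pd.DataFrame(
        columns=["bait", "candidate", "n_models_retained", "methods",
                 "consensus_methods", "consensus_supported", "best_weighted"]
    )


def localization_compatibility(pair: tuple[str, str],
                               annotations: dict[str, set[str]]) -> str:
    """Tri-state subcellular-localization compatibility of a protein pair.

    ``yes`` when compartment sets intersect or both proteins occupy
    cytosol-adjacent compartments (an ER membrane protein can meet a
    cytosolic one); ``no`` when the only shared geography is across a
    membrane (ER lumen vs cytosol); ``unknown`` when either protein lacks
    annotation.
    """
    a = {c.strip().lower() for c in annotations.get(pair[0], set())}
    b = {c.strip().lower() for c in annotations.get(pair[1], set())}
    if not a or not b:
        return "unknown"
    if a & b:
        return "yes"
    if (a & _CYTOSOL_ADJACENT) and (b & _CYTOSOL_ADJACENT):
        return "yes"
    return "no"


def membrane_plausibility(model, chain_a: str, chain_b: str,
                          tm_annotations: list[DomainAnnotation],
                          frame: MembraneFrame | None = None,
                          config: ScoringConfig | None = None) -> str:
    """Flag interfaces engaging a transmembrane segment as implausible.

    ``no`` when any interface residue of the pair lies inside an annotated
    TM range (optionally corroborated by membrane proximity when a frame
    is given); ``yes`` otherwise; ``unknown`` without TM annotations.
    The flag never excludes a record on its own.
    """
    if not tm_annotations:
        return "unknown"
    config = config or ScoringConfig()
    iface = find_interface(model, chain_a, chain_b, config)
    in_tm = set()
    for ann in tm_annotations:
        members = iface.residues_a if ann.protein_id == chain_a else (
            iface.residues_b if ann.protein_id == chain_b else set())
        in_tm |= {(ann.protein_id, r) for r in members
                  if ann.start <= r <= ann.end}
    if not in_tm:
        return "yes"
    if frame is not None:
        near = membrane_proximal_residues(model, frame, config)
        if not (in_tm & near):
            # annotated TM engaged but far from the membrane plane: still
            # implausible geometry
            return "no"
    return "no"


def read_localization_table(path: str | Path) -> dict[str, set[str]]:
    """TSV with columns protein_id, compartment (one row per annotation)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "compartment"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.protein_id), set()).add(str(r.compartment))
    return out
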