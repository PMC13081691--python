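#!/usr/bin/env python
"""Amphipathicity of the membrane-proximal SAC1 helix.

Scores the SAC1 segment adjoining the ER bilayer (residues 119-135,
FLAMLNHVLNVDGFYFST) on the Fauchère–Pliska scale alongside two reference
segments: a classic amphipathic helix (magainin 2) and a polar control.
Mean hydrophobicity ⟨H⟩ measures overall membrane affinity; the
hydrophobic moment μH measures how strongly hydrophobic residues segregate
onto one helix face.

Writes results/helix_metrics.tsv."""

from pathlib import Path

import pandas as pd

from foldscreen.helix_metrics import analyze_segment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SEGMENTS = {
    # SAC1 residues 119-135, the helix sitting on the upper leaflet
    "SAC1_119-135": ("FLAMLNHVLNVDGFYFST", 119),
    # magainin 2: textbook amphipathic helix, high moment
    "magainin2": ("GIGKFLHSAKKFGKAFVGEIMNS", 1),
    # polar control: hydrophilic, low mean and moment
    "polar_control": ("SSNNDDQQEEKKRRTT", 1),
}


def main() -> None:
    rows = []
    for name, (seq, start) in SEGMENTS.items():
        seg = analyze_segment(seq, start=start)
        rows.append({
            "segment": name, "sequence": seg.sequence,
            "start": seg.start, "end": seg.end,
            "mean_h": round(seg.mean_h, 2), "mu_h": round(seg.mu_h, 2),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "helix_metrics.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"-> {RESULTS / 'helix_metrics.tsv'}")


if __name__ == "__main__":
    main()
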