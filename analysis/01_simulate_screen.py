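#!/usr/bin/env python
"""Generate the synthetic bait-candidate screen used by the downstream
analysis steps: 48 dimer models, half constructed true-like (low interchain
PAE, docked interface, confident ipTM) and half false-like (interchain PAE
far above the 15 Å cutoff).

Structures and confidence JSONs are bulky intermediates and go under
scratch/; the manifest location is printed for step 02.
"""

from pathlib import Path

import pandas as pd

from foldscreen.synthetic_data import make_screen_fixture

ROOT = Path(__file__).resolve().parents[1]
OUTDIR = ROOT / "scratch" / "screen_fixture"
SEED = 42


def main() -> None:
    manifest = make_screen_fixture(n_pairs=48, frac_true=0.5, seed=SEED,
                                   outdir=OUTDIR)
    labels = pd.read_csv(OUTDIR / "labels.tsv", sep="\t")
    counts = labels.label.value_counts().to_dict()
    print(f"wrote {len(labels)} synthetic dimers to {OUTDIR}")
    print(f"ground truth: {counts}")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
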