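#!/usr/bin/env python
"""Redesign the top candidate of each mode-of-action stratum by greedy
single-substitution hill-climbing (max two substitutions, mirroring the
two-change redesigns of server-side peptide-design tools).

The scorer here is the transparent additive Eisenberg-hydrophobicity demo
scorer; with a trained ACP model the same search applies unchanged.
"""

import json
from pathlib import Path

from pepscreen.properties import EISENBERG
from pepscreen.redesign import additive_scorer, diff, redesign

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = json.loads((ROOT / "screen_report.json").read_text())
    scorer = additive_scorer(EISENBERG)
    out = {}
    for cat, peps in report["top_candidates"].items():
        if not peps:
            continue
        res = redesign(peps[0], scorer, max_rounds=2)
        subs = [str(s) for s in res.substitutions]
        out[cat] = {
            "original": res.original,
            "variant": res.variant,
            "substitutions": subs,
            "original_score": round(res.original_score, 3),
            "variant_score": round(res.variant_score, 3),
            "highlighted": res.highlighted(),
        }
        print(f"{cat}: {res.original} -> {res.highlighted()} "
              f"({', '.join(subs) or 'no change'}; "
              f"score {res.original_score:.2f} -> {res.variant_score:.2f})")
        assert diff(res.original, res.variant) == list(res.substitutions)
    (ROOT / "redesigns.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {len(out)} redesigns -> {ROOT / 'redesigns.json'}")


if __name__ == "__main__":
    main()
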