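#!/usr/bin/env python
"""Consensus-screen the scored peptidome, stratify by mode of action, and
rank candidates within each stratum.

Writes verdicts.tsv, venn.tsv and screen_report.json under results/ and
prints the headline counts.
"""

import json
from pathlib import Path

import pandas as pd

from pepscreen import screening as sc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = sc.read_scores_tsv(ROOT / "inputs" / "scores.tsv")
    verdicts = sc.screen_table(rows)
    sc.write_verdicts_tsv(verdicts, ROOT / "verdicts.tsv")

    venn = sc.venn_counts(verdicts)
    moa = sc.classify_moa(verdicts)
    pd.DataFrame([venn]).T.rename(columns={0: "count"}).to_csv(
        ROOT / "venn.tsv", sep="\t"
    )

    print(f"screened {len(rows)} unique peptides:")
    print(f"  AntiCP positive: {venn['anticp_total']}")
    print(f"  iACP positive:   {venn['iacp_total']}")
    print(f"  MLACP positive:  {venn['mlacp_total']}")
    print(f"  consensus ACPs:  {venn['consensus']}")
    print(f"mode of action among consensus ACPs: "
          f"toxic-only {moa['toxic_only']}, CPP-only {moa['cpp_only']}, "
          f"both {moa['both']}, none {moa['none']}")

    consensus = [v.peptide for v in verdicts if v.consensus_acp]
    summary = sc.property_summary(consensus)
    if not summary.empty:
        print(f"consensus-set properties (n={summary.n}): "
              f"{summary.length_pct.get('5-20', 0)}% short (5-20 aa), "
              f"{summary.hydro_pct.get('hydrophilic', 0)}% hydrophilic, "
              f"{summary.charge_pct.get('cationic', 0)}% cationic")

    by_pep = {s.peptide: s for s in rows}
    top = {}
    for cat in sc.MOA_CATEGORIES:
        members = [by_pep[v.peptide] for v in verdicts
                   if v.consensus_acp and v.moa_category == cat]
        ranked = sc.rank_candidates(members)
        top[cat] = [r.peptide for r in ranked[:3]]
        if ranked:
            best = ranked[0]
            print(f"  top {cat}: {best.peptide} (SVM {best.anticp_svm:.2f})")

    report = {
        "n_screened": len(rows),
        "venn": venn,
        "moa": moa,
        "property_summary": None if summary.empty else {
            "length_pct": summary.length_pct,
            "hydro_pct": summary.hydro_pct,
            "charge_pct": summary.charge_pct,
        },
        "top_candidates": top,
    }
    (ROOT / "screen_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
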