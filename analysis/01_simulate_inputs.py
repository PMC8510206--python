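#!/usr/bin/env python
"""Generate the synthetic study inputs: a proteome FASTA, predictor score
tables with hidden truth labels, and MTT plates for every scenario.

All downstream drivers read from results/inputs/.
"""

from pathlib import Path

from pepscreen import digestion as dg
from pepscreen import synthetic as syn

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    proteins = syn.gen_proteome(n_proteins=120, seed=syn.stage_seed(SEED, "proteome"))
    syn.write_fasta(proteins, OUT / "proteome.fasta")
    print(f"proteome: {len(proteins)} proteins -> {OUT / 'proteome.fasta'}")

    peptides = dg.digest_proteome(proteins)
    scores, truth = syn.gen_scores(
        [p.sequence for p in peptides], seed=syn.stage_seed(SEED, "scores")
    )
    scores.to_csv(OUT / "scores.tsv", sep="\t", index=False)
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"scores: {len(scores)} peptides scored -> {OUT / 'scores.tsv'}")
    print(f"  (hidden truth labels kept separately in truth.tsv; "
          f"{int(truth.is_acp.sum())} latent ACPs)")

    for name, scenario in syn.SCENARIOS.items():
        plate = syn.gen_mtt(scenario, seed=syn.stage_seed(SEED, "mtt"))
        plate.to_csv(OUT / f"plate_{name}.tsv", sep="\t", index=False)
        print(f"MTT plate {name}: {len(plate)} wells -> plate_{name}.tsv")

    combo = syn.gen_combo_mtt(seed=syn.stage_seed(SEED, "combo"), interaction=0.9)
    combo.to_csv(OUT / "combo_grid.tsv", sep="\t", index=False)
    print(f"combination grid: {len(combo)} replicate measurements -> combo_grid.tsv")


if __name__ == "__main__":
    main()
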