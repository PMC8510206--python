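# pepscreen

Virtual screening of anticancer peptides (ACPs) from an in silico pepsin
hydrolysate, with MTT dose–response validation analysis.

Protein hydrolysates are a practical source of bioactive peptide
candidates: digesting a proteome with a gastric protease yields thousands
of short peptides, a handful of which may selectively inhibit cancer
cells. `pepscreen` implements that screening funnel end to end for
researchers triaging peptide candidates before synthesis:

1. **Digestion** — parse a protein FASTA and apply a configurable protease
   rule (default pepsin, pH 1.3: cut C-terminal to F/L unless proline
   follows), keeping unique peptides of 5–50 residues.
2. **Physicochemistry** — net side-chain charge (K/R = +1, D/E = −1),
   GRAVY (Kyte–Doolittle mean hydropathy), Eisenberg hydrophobic moment
   μH = (1/N)·|Σᵢ hᵢ·e^(iδ·i)| at δ = 100°/residue, and residue
   composition.
3. **Consensus screening** — a peptide is a putative ACP only if three
   independent predictors agree: an AntiCP-style SVM score > 1.00, an
   iACP-style probability > 0.5, and both MLACP-style RF and SVM
   probabilities > 0.5. Consensus ACPs are stratified by predicted mode of
   action (toxic / cell-penetrating / both / neither) and ranked.
4. **Redesign** — greedy single-substitution hill-climbing under any
   scorer, reproducing the "suggest ≤ 2 point substitutions" behaviour of
   server-side peptide-design tools.
5. **Dose–response** — MTT viability
   `% = 100·(A_treated − A_blank)/(A_control − A_blank)`, four-parameter
   logistic fits `V(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)`,
   one-way ANOVA with Dunnett's many-to-one test, and peptide × drug
   combination-grid analysis.
6. **Synthetic data** — seeded generators for proteomes, predictor score
   tables with hidden truth labels, and MTT plates, so the whole pipeline
   is testable without network access or wet-lab data.

Trained ACP predictors are deliberately *not* reimplemented: score tables
are external inputs (TSV), and the pipeline treats the predictors as
pluggable score sources.

## Worked example

The `analysis/` drivers run the full study on synthetic inputs
(`python analysis/01_simulate_inputs.py` through `06_combination.py`).
A 120-protein synthetic proteome digests into 3,203 unique 5–50 aa
peptides, dominated by the short bin as expected for a frequent cutter:

```
120 proteins -> 3203 unique peptides (5-50 aa)
   5-20 aa:  2481  (77.5%)
  21-35 aa:   576  (18.0%)
  36-50 aa:   146  (4.6%)
```

Consensus screening of the simulated score table keeps 119 of 3,203
peptides and stratifies them by mode of action:

```
  AntiCP positive: 293
  iACP positive:   531
  MLACP positive:  133
  consensus ACPs:  119
mode of action among consensus ACPs: toxic-only 0, CPP-only 94, both 4, none 21
```

Fitting the simulated MTT plates recovers each scenario's behaviour: the
active peptide shows a clean dose response, the inactive redesign is
flagged rather than assigned a meaningless IC50, and doxorubicin fits in
the sub-µM range:

```
C-ori: IC50 = 117.07 uM (hill 1.54, bootstrap SD 3.20)
C-rds: flat viability across doses -> no IC50 (no-inhibition flag)
doxorubicin: IC50 = 0.12 uM (hill 1.21, bootstrap SD 0.01)
```

The same steps are scriptable from the shell:

```bash
pepscreen simulate proteome --seed 17 --out work/
pepscreen digest --fasta work/proteome.fasta --rule pepsin_pH1.3 --out work/peptides.tsv
pepscreen screen --scores work/scores.tsv --out work/verdicts.tsv --report work/report.json
pepscreen mtt-fit --plate work/plate.tsv --compound C-ori --timepoint 72 --fix-bottom 0 --out work/fit.json
pepscreen run --config run.yaml   # whole workflow from one YAML config
```

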