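# cappedpep

Prediction, targeted mass-spectrometry detection, and downstream analysis of
**capped peptides** — fragments of classically secreted proteins that carry an
N-terminal pyroglutamate (pGlu) and a C-terminal amide as chemical "caps".
Known hormones with this chemistry include TRH (pGlu-HP-NH2) and GnRH
(pGlu-HWSYGLRPG-NH2); the same motif marks many additional candidate signaling
peptides in mouse and human plasma.

The package is aimed at peptidomics groups running targeted
LC-QTOF / LC-QQQ workflows against synthetic peptide standards.

## What it computes

**Prediction.** A C-terminal amidation site is marked by a Gly-dibasic
tripeptide G[K/R]R (the glycine is the amide donor, K/R-R the convertase
site). For every motif at position *g* in a secreted precursor, every
glutamine at position *q* with 2 ≤ *g* − *q* ≤ 20 defines a candidate
peptide `seq[q..g−1]` whose mature form is `pGlu-<seq[q+1..g−1]>-NH2`.

**Chemistry.** Neutral monoisotopic mass M = Σ residue masses + H₂O +
Δ(pGlu: −17.0265) + Δ(amide: −0.9840); the two caps cancel the water term
exactly. Ions: m/z = (M + z·1.007276)/z; b/y fragment series with the caps on
their respective termini; vendor-neutral MRM transition lists.

**Detection.** Two-step targeted rules against an authentic standard:
MS1 match within 20 ppm and 1 min co-elution; MRM validation at
chromatographic S/N > 2.5 (matched-filter peak height over a 1.4826·MAD
noise scale) with co-eluting apex; optional MS/MS confirmation by ≥ 1
daughter ion. Concentrations are back-calculated from an external standard
curve (OLS of area on concentration).

**Downstream.** Amino-acid composition versus a reference hormone set
(two-sided t-tests), flanking-residue frequency maps, condition fold-change
tables, tissue-expression z-score matrices with hierarchical clustering,
4-parameter-logistic EC50 fits, exponential-decay half-lives, cross-species
conservation and an identity-distance guide tree.

Every stage is testable against the bundled synthetic-data generators
(`cappedpep.synthetic`), which plant candidates, MS features, fold changes
and curve parameters with recorded ground truth.

## Worked example

```python
from cappedpep import (ProteinRecord, predict_capped_peptides,
                       peptide_mass, ion_mz, fragment_ions, CAPPED_MODS)

# the tachykinin precursor region ...RRPKPQQFFGLMGKR...
rec = ProteinRecord("TAC1", "RRPKPQQFFGLMGKR")
for c in predict_capped_peptides(rec):
    print(c.capped_notation, c.start, c.end, c.length)

m = peptide_mass("QFFGLM", CAPPED_MODS)
print(round(m, 4), round(ion_mz(m, 1), 4))
print({f.annotation: round(f.mz, 3) for f in fragment_ions("QFFGLM", CAPPED_MODS)
       if f.annotation == "b4+"})
```

prints

```
pGlu-QFFGLM-NH2 6 12 7
pGlu-FFGLM-NH2 7 12 6
723.3414 724.3487
{'b4+': 463.198}
```

Both glutamines upstream of the GKR motif seed a candidate; the 6-mer is the
tachykinin-like capped peptide whose singly protonated parent (m/z 724.3487)
and b4 fragment (m/z 463.2) are the usual MRM pair. From a FASTA secretome
the same scan runs via the CLI:

```bash
cappedpep predict --fasta secretome.fasta --out preds.tsv
cappedpep transitions --preds preds.tsv --out mrm.csv
cappedpep run --config cfg.yaml --out rundir/   # full discovery pipeline
```

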