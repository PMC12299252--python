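# screenclean

A toolkit for curating public bioactivity data and triaging
virtual-screening hits, built around an assay-aware duplicate-resolution
algorithm ("selective cleaning"). When a molecule has several reported
IC50 values, naive conventions (take the maximum, average, most recent,
random) can latch onto outliers from rarely-used assay procedures.
Selective cleaning instead restricts each molecule's records to its most
*globally prevalent* assay and only then keeps the maximum pIC50 —
trading a little optimism for much better consistency.

## What's in the box

| module | purpose |
| --- | --- |
| `screenclean.activity_io` | CSV/TSV activity, docking-score and interaction tables with explicit column maps (ChEMBL preset included) |
| `screenclean.curation` | structure standardization, IC50→pIC50 conversion, null/censored handling, molecular-weight filter (100 < MW < 750 by default) |
| `screenclean.selective_cleaning` | the two-layer duplicate resolution, a brute-force oracle, and the four naive baselines |
| `screenclean.splitting` | Bemis–Murcko scaffold split and seeded random split |
| `screenclean.bench` | RDKit 2D-descriptor featurization, k-fold CV over a pluggable learner registry, curation-strategy comparison |
| `screenclean.triage` | pIC50/affinity region gate plus structural admissibility rules (sigma-hole donor, 2–4 aromatic rings, flexibility cap, peptide/nucleotide/fatty-acid exclusions) |
| `screenclean.postdock` | p1−p2 site-selectivity deltas, rank-mean consensus over docking engines, interaction-energy classification (−/+/++/+++) |
| `screenclean.synthdata` | synthetic multi-assay activity tables with known latent potencies, Zipf assay prevalence, assay bias, noise and stereo duplicates |

## CLI

All stages are exposed through one `screenclean` entry point:

```bash
screenclean convert  --in export.csv --colmap chembl --out raw.csv
screenclean clean    --in raw.csv  --out std.csv  --report clean.json
screenclean filter   --in std.csv  --out filt.csv --mw-low 100 --mw-high 750
screenclean scclean  --in filt.csv --out sc.csv   --report sc.json   # or --strategy global_max
screenclean split    --in sc.csv   --mode scaffold --fractions 0.9,0,0.1 --seed 7 --out splits.json
screenclean bench    --in sc.csv   --model gbr --k 5 --seed 11 --out bench.json
screenclean compare  --strategies std=std.csv,sc=sc.csv --baseline std --final sc
screenclean triage   --in predictions.csv --out hits.csv [--sdf hits.sdf]
screenclean dock-report --scores scores.csv --out report.json
screenclean profile  --interactions nci.csv --reference AT --out profile.json
screenclean simulate --out raw.csv --truth truth.json --seed 4
screenclean recover  --strategies sc,global_max --reps 100 --seed 3 --out recovery.json
```

`simulate`/`recover` accept a YAML config whose keys mirror
`synthdata.SyntheticConfig` (molecule count, assay count, Zipf exponent,
duplication rate, assay-bias and noise scales, rare-assay bias, stereo
duplication rate).

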