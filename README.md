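# sialoscreen

Screening toolkit for **intramolecular trans-sialidases (IT-sialidases,
EC 4.2.2.15)** in bacterial genomes and gut metagenomes, with the enzyme
kinetics needed to characterise them.

Most bacterial sialidases are hydrolytic: they release free N-acetylneuraminic
acid (Neu5Ac) from host sialoglycans. IT-sialidases instead release
2,7-anhydro-Neu5Ac, a bicyclic product other gut microbes cannot readily use —
a "selfish" mode of mucosal sialic-acid harvesting. Structurally, the two
classes are distinguished by a β-strand **I-domain inserted inside the GH33
catalytic domain**: in a profile-HMM search, a hydrolytic enzyme matches the
GH33 sialidase model as one contiguous alignment, while an IT-sialidase
matches it as a *segmented* alignment whose gap houses a separate I-domain
hit. `sialoscreen` implements this screen end to end:

* **profile_hmm** — build profile HMMs from seed alignments, score proteins
  with local-mode Viterbi (bits), calibrate Gumbel E-value statistics on
  random background sequences, and report all non-overlapping domain hits
  with per-domain E-value ≤ 10⁻⁴ (iterative envelope masking, so split and
  tandem domains yield multiple hits). HMMER3 ASCII profiles can be imported.
* **domain_architecture** — per-protein calls: `NONE`, `HYDROLYTIC_TYPE`
  (GH33 hit only) or `IT_SIALIDASE` (GH33 + I-domain co-occurrence), with
  segmented-match evidence and CBM40 (sialic-acid-binding module) flags.
* **genome_screen** — locate NanA/NanK/NanE1 genes on gene tables and call a
  canonical sialic-acid catabolism cluster when all three fall within **15
  consecutive loci** on one replicon (intervening genes allowed); call the
  Bacteroides-type alternative pathway (NanL-like aldolase + NanE2 + RokA);
  aggregate screen-level percentages.
* **metagenome_screen** — per-sample and per-group prevalence of sialidase /
  I-domain hits over cohorts of translated coding sequences (sequence-level
  search at reduced scale, or count-level arithmetic at full published scale),
  plus a Fisher-exact group contrast.
* **kinetics** — Michaelis–Menten with uncompetitive substrate inhibition
  `v = Vmax·S / (KM + S(1 + S/Ki))`, the integrated first-order rate law
  `ln(S₀/Sₜ) = k·t` with `k = (kcat/KM)·[E]`, and log-logistic IC50 fits
  `y = 100 / (1 + 10^(log₁₀[I] − logIC50))`.
* **synthetic_data** — seeded generators for every input with truth labels:
  proteomes with planted hydrolytic/IT architectures, gene tables with planted
  Nan clusters at controlled spans, cohorts with specified positivity rates,
  kinetic datasets from the stated rate laws.
* **workflows / cli** — orchestration plus the `sialoscreen` command
  (`build-hmm`, `calibrate`, `search`, `classify`, `screen-genomes`,
  `screen-metagenome`, `simulate`, `kinetics-fit`).

## Worked example

Screen a seeded synthetic proteome (180 decoys, 20 hydrolytic sialidases,
20 IT-sialidases) and classify every protein:

```python
import sialoscreen as ss
from sialoscreen import synthetic_data as synth
from sialoscreen.domain_architecture import classify_proteome

models = synth.default_models(seed=7)
for name in ("sialidase", "I-domain", "CBM40"):
    ss.calibrate(models[name], n_random=500, seed=11)

records, truth = synth.make_proteome(
    synth.ProteomeSpec(n_background=180, n_hydrolytic=20, n_it=20, seed=3), models)
hits = []
for name in ("sialidase", "I-domain", "CBM40"):
    hits += ss.search_domains(models[name], records, max_evalue=1e-4)
calls = classify_proteome(hits, all_target_ids=[r[0] for r in records])

from collections import Counter
print(Counter((t, calls[p].call.value) for p, t in zip(truth.protein_id, truth.label)))
```

prints

```
Counter({('NONE', 'NONE'): 180,
         ('IT_SIALIDASE', 'IT_SIALIDASE'): 20,
         ('HYDROLYTIC_TYPE', 'HYDROLYTIC_TYPE'): 20})
```

— every planted architecture is recovered and no decoy is called an
IT-sialidase. Fit the substrate-inhibition model to rate data and derive the
catalytic efficiency:

```python
import numpy as np
from sialoscreen.kinetics import RateDataset, fit_substrate_inhibition

S = np.array([0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 4.0, 7.0, 10.0])
data = synth.make_kinetic_dataset(
    "substrate_inhibition",
    {"vmax": 1.37, "km": 0.59, "ki": 2.37, "enzyme_conc": 0.2206}, S)
fit = fit_substrate_inhibition(data)
print(f"Vmax={fit.vmax:.2f} uM/min  KM={fit.km:.2f} mM  Ki={fit.ki:.2f} mM  "
      f"kcat={fit.kcat:.3g} /min  kcat/KM={fit.kcat_over_km:.3g} /(min mM)")
```

prints

```
Vmax=1.37 uM/min  KM=0.59 mM  Ki=2.37 mM  kcat=6.21e+03 /min  kcat/KM=1.05e+04 /(min mM)
```

`Ki < KM·10` here signals pronounced substrate inhibition: the rate peaks at
`S* = sqrt(KM·Ki) ≈ 1.2 mM` and declines at higher substrate.

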