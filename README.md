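# hemidyad

Dyad-resolved DNA hemi-methylation calling from the fragment geometry of a
methylation-dependent restriction enzyme digest.

## The problem

At a CpG (or CHG) dyad the two strands of the double helix each carry a
cytosine, and the pair can be **unmethylated**, **hemi-methylated** on
either strand, or **fully methylated**. Hemi-methylation is abundant —
it arises during replication and de novo methylation and can act as an
epigenetic mark — but bisulfite-based dyad assays (hairpin bisulfite
sequencing) degrade DNA and destroy sequence variants.

The enzyme **MspJI** offers a bisulfite-free route: it recognizes a
methylated `CNNR` motif (R = A/G) and cleaves 9/13 nt downstream,
leaving a 4 nt 5′ overhang. Inside the palindromic context
`YNCGNR` (Y = C/T) *both* cytosines of a CpG dyad sit in their own CNNR
motif, so each strand's methyl mark independently places one cut:

* fully methylated dyad → cuts on both sides → a characteristic **32 bp**
  fragment with the dyad context at its center;
* hemi-methylated dyad → one cut → a longer fragment whose edge sits
  exactly 13 bp downstream of the motif on the methylated strand;
* unmethylated dyad → no cut → the dyad is spanned intact.

Reading fragment edges therefore resolves the four dyad states without
base conversion. On an i.i.d. random genome one quarter of CpG dyads
satisfy the `YNCGNR` constraint; the analogous `YCWGR` context (W = A/T)
covers CHG dyads.

## What the package does

* **Cut model & simulator** (`hemidyad.digestion`) — breakpoints at
  Watson `c + 17` / Crick `c − 16` (the far, 13 nt cut defines the
  repaired fragment edge), per-site cutting efficiencies by motif class
  (`CGNG` ≈ 0.97, `CGNA` ≈ 0.80), size selection, 32-mer purification
  efficiency `E_pu`, UMIs, PCR duplicates, plus a whole-genome in-silico
  digest (stochastic 0/1 cut assignment, fragment-length histogram).
* **Dyad caller** (`hemidyad.caller`) — position+UMI deduplication, exact
  edge matching of fragments against each resolvable dyad's cut offsets,
  four-status counts with a coverage floor of 5 reads, and strand-level
  methylation levels at every `CNNR` cytosine.
* **Normalization** (`hemidyad.normalization`) — the four expected-count
  equations
  `M_exp = M·E_W·E_C·E_pu`, `W_exp = W + M·E_W·(1−E_C)`,
  `C_exp = C + M·(1−E_W)·E_C`, `U_exp = U + M·(1−E_W)·(1−E_C)`
  and their per-dyad inversion (efficiencies assigned from each strand's
  downstream R base).
* **Hairpin-bisulfite oracle** (`hemidyad.hairpin`) — simulates the
  strand-paired bisulfite readout of the same molecules, estimates the
  conversion rate from linker cytosines, and calls dyads by the
  predominant status (≥ 3 observations, ties excluded) for
  cross-validation of the fragment-geometry caller.
* **Downstream analysis** (`hemidyad.analysis`) — motif cluster
  classification (1 unme / 2 motif-strand hemi / 3 opposite-strand hemi /
  4 me), orientation-aware hemi-methylation profiles, mean signal over
  motif-centered windows, and allele-specific methylation testing
  (two-sided binomial test at coverage > 10, Benjamini–Hochberg FDR,
  bias at q < 0.05).
* **Synthetic data** (`hemidyad.synthetic`) — seeded genomes, designed
  methylomes with per-dyad truth tables, the 146 bp worked-example
  construct, and allele models, so the whole pipeline is testable offline.

## Worked example

The classic validation digest: a 146 bp duplex with a single resolvable
CpG dyad (Watson C at 0-based 72).

```python
import numpy as np
from hemidyad import (
    DigestionParams, breakpoints_for_molecule, digest_molecule,
    plant_construct, sample_molecules,
)
from hemidyad.synthetic import make_construct_methylome

genome, dyad = plant_construct(seed=0)
unit = DigestionParams(efficiency_by_r={"G": 1.0, "A": 1.0})
for label, (w, c) in {"fully methylated": (True, True),
                      "Watson-hemi": (True, False),
                      "unmethylated": (False, False)}.items():
    methylome = make_construct_methylome(genome, dyad, w, c)
    (molecule,) = sample_molecules(methylome, 1, seed=0)
    bps = breakpoints_for_molecule(genome, methylome, molecule, unit,
                                   rng=np.random.default_rng(0))
    lengths = [e - s for s, e in digest_molecule(146, bps["construct"])]
    print(f"{label:>17}: fragments {lengths}")
```

prints

```
 fully methylated: fragments [57, 32, 57]
      Watson-hemi: fragments [89, 57]
     unmethylated: fragments [146]
```

— both cuts fire on the fully methylated dyad (57 + 32 + 57), only the
Watson-side cut fires on the hemi dyad (89 + 57), and the unmethylated
duplex stays intact. Simulating a 20-molecule Watson-hemi library and
calling it back recovers the state at full coverage:

```
 watson_c  unme  hemiW  hemiC  me  coverage  excluded
       72     0     20      0   0        20     False
```

The same pipeline is available from the shell: `hemidyad make-fixtures`,
`simulate`, `call`, `normalize`, `hairpin`, `analyze`, `profile`, `asm`
(see `hemidyad --help`).

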