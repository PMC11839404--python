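# adnaplace

Ancient-DNA damage simulation and phylogenetic placement accuracy
assessment, in one self-contained Python package.

## The problem

DNA recovered from archaeological, paleontological, or sediment samples is
degraded: post-mortem nicks shred molecules into short fragments, and
cytosine deamination in single-stranded overhangs produces the
characteristic C→T misincorporations near 5′ read ends (and, through
library preparation of double-stranded libraries, G→A near 3′ ends).
A central task with such reads is taxonomic identification, and
*phylogenetic placement* — assigning a read to a branch of a fixed
reference tree — is an attractive tool for it because it can place reads
from extinct or unsampled lineages onto internal branches. But how much
does aDNA damage hurt placement accuracy, and which damage process is to
blame? `adnaplace` provides the machinery to answer that question with
controlled simulations: a transparent damage simulator, placement accuracy
metrics, and a pruning-based benchmark harness, all runnable on synthetic
data with no external tools or downloads.

## The model

Damage follows the Briggs model of double-stranded-library aDNA damage,
with four parameters:

* **ν** — nick probability per junction between consecutive bases;
  fragment lengths are therefore geometric with median
  ⌊−ln 2 / ln(1 − ν)⌋;
* **λ** — success probability of the geometric overhang-length
  distribution, support {0, 1, 2, …} (λ = 1 ⇒ always length 0);
* **δ<sub>ss</sub>** — deamination probability per eligible base in the
  single-stranded overhang;
* **δ<sub>ds</sub>** — deamination probability per eligible base in the
  double-stranded remainder.

Each read gets one overhang, 5′ or 3′ with equal probability; a
5′-overhang read accumulates only C→T changes, a 3′-overhang read only
G→A. Aligned input is supported: gaps travel with the reads, are never
damaged, and are excluded from length accounting, so damaged reads stay
in alignment with their source — which lets damage be injected *after*
alignment, isolating damage effects from alignment error.

Placement accuracy is scored topologically. For a read placed on branches
p with likelihood weight ratios LWR(p), against true branch t:

* **ND** = node distance between the best (highest-LWR) branch and t
  (0 for the same branch, 1 for branches sharing a node, …);
* **eND** = Σ<sub>p</sub> LWR(p) · d(p, t), the expectation of ND under
  the reported placement weights;
* **normalized eND** = eND / tip count, comparable across trees.

The benchmark loop mirrors placement-accuracy pipelines: prune a random
subtree (its sequences become queries with a known true attachment
branch), damage the aligned queries, place them back (a built-in naive
Hamming/softmax placer keeps the loop self-contained; external jplace
results can be ingested instead), and assess ND/eND against the truth.

## Worked example

```python
import numpy as np
import adnaplace as ap

rng = np.random.default_rng(0)
source = ap.random_sequence(20_000, 0.4, rng, "mito")      # 20 kb, GC 0.4
params = ap.DamageParameters(nu=0.025, lam=0.15,
                             delta_ss=0.65, delta_ds=0.015)
reads, log = ap.simulate([source], params, seed=0)

lengths = [r.nongap_length for r in reads]
print(len(reads), int(np.median(lengths)),
      ap.theoretical_median_fragment_length(0.025))
# 367 41 27
rates = [ap.per_read_error_rate(r) for r in reads]
print(f"{100 * np.mean(rates):.1f}%")
# 2.2%
```

367 reads survive the default filters (≥ 15 bp non-gap, ≥ 10 reads per
source). Their median length (41 bp) exceeds the unfiltered theoretical
median (27 bp) exactly because the short tail was filtered away. The mean
per-read error rate of 2.2% shows deamination touches few sites even at
these high damage rates — fragmentation, not misincorporation, is what
removes information.

The same effect shows up downstream. On a 32-taxon synthetic dataset:

```python
tree, aln = ap.make_fixture(ap.FixtureSpec(seed=0))
grid = ap.ParameterGrid(nu=(0.0005, 0.025), lam=(1.0,),
                        delta_ss=(0.0,), delta_ds=(0.0,))
res = ap.run_experiment(aln, tree, grid, n_prunings=5, seed=1)
print(res.groupby("nu")["normalized_end"].median())
# nu
# 0.0005    4.961226e-11
# 0.0250    3.225808e-02
```

Near-intact queries (ν = 0.0005) place essentially perfectly; heavy
nicking (ν = 0.025, i.e. ~27 bp reads) visibly degrades accuracy, with
no deamination involved at all.

The same functionality is available from the shell, e.g.:

```bash
adnaplace damage -i in.fasta -o reads.fasta --log damage.tsv \
    --nu 0.025 --lam 0.15 --dss 0.65 --dds 0.015 --seed 1
adnaplace medians --nu 0.001,0.025     # theoretical median read lengths
adnaplace make-fixture --n-taxa 32 --out-dir fx
adnaplace experiment --tree fx/tree.nwk --msa fx/alignment.fasta \
    --grid-nu 0.0,0.025 --n-prunings 10 --seed 1 -o results.tsv
adnaplace fit --results results.tsv    # standardized eND ~ ν+λ+δds+δss
```

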