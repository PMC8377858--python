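# pegrank

Automated pegRNA/ngRNA design for prime editing, ranked by predicted
editing efficiency.

Prime editors install arbitrary small edits (substitutions, insertions,
deletions) from a pegRNA whose 3′ extension both primes reverse
transcription (PBS) and templates the edit (RTT). Picking the spacer,
PBS length, RTT length and the optional PE3/PE3b nicking guide is a
large combinatorial choice that strongly affects efficiency. `pegrank`

1. **initiates** — finds every 20-nt spacer with an NGG PAM, on either
   strand, whose nick lies 5′ of the edit within a ±200-bp window;
2. **expands** — enumerates all spacer × PBS (8–17 nt) × RTT (10–30 nt)
   × ngRNA (±150 nt, including PE3b) combinations whose RTT covers the
   edit with enough downstream homology;
3. **ranks** — extracts 23 features per design — Cas9 activity, PBS/RTT
   length and GC, PAM disruption (`is_dPAM`), PE3b status, edit
   mismatch/ins/del counts, the nick-relative positions `Target_pos`,
   `ngRNA_pos`, `Target_end_flank`, and RNA-folding disruption scores
   `D(1)..D(10)` — and scores each design with gradient-boosted tree
   models (separate PE2 / PE3 models);
4. **reports** — a ranked tab-delimited table, plus a skip table for
   undesignable variants.

The folding disruption score of extension position *i* is
`D(i) = max_j P(i, j)` over scaffold positions *j*, where P is the
equilibrium base-pair probability matrix of the whole pegRNA — high
D(i) flags extensions (the classic first-base C pairing the scaffold
G81) likely to deform the scaffold structure. Models are trained and
evaluated with *grouped nested cross-validation*: outer folds split by
target mutation (position + allele) so no mutation leaks between train
and test, inner folds tune the XGBoost grid; feature importance is mean
|SHAP|. See `docs/methods.md` for the full model description.

## Worked example

Generate deterministic toy fixtures, train small models on simulated
screens, and design:

```python
import numpy as np
from pegrank import *
from pegrank.simulate import SimConfig, simulate_training_table

t3 = simulate_training_table(SimConfig(seed=11, n_variants=8, designs_per_variant=30))
t2 = simulate_training_table(SimConfig(seed=12, n_variants=8, designs_per_variant=30, system="PE2"))
rng = np.random.default_rng(0)
m3 = train_test_split_train(t3, np.where(rng.random(len(t3)) < 0.8, "train", "test"), system="PE3")
m2 = train_test_split_train(t2, np.where(rng.random(len(t2)) < 0.8, "train", "test"), system="PE2")
save_model(m3, "pe3.json"); save_model(m2, "pe2.json")
make_toy_locus(1).write("toy.fa", "toy.vcf")
```

```sh
$ pegrank design toy.vcf --reference toy.fa \
      --model-pe2 pe2.json --model-pe3 pe3.json -o designs.tsv --top-n 2
8 designs for 4 variants -> designs.tsv; 1 skipped -> skipped.tsv
```

Top-ranked design per variant (columns abridged):

```
variant_id strand target_pos ngrna_pos is_PE3b is_dPAM pbs_len rtt_len predicted_efficiency
single     +      10         0         0       0       16      27      51.97
multi      -      12         0         0       0       17      29      60.20
pe3b       +      10         2         1       0       17      30      74.22
dpam       +      5          0         0       1       8       27      35.26
```

Each row is one pegRNA (spacer, PBS, RTT, full pegRNA sequence) with
its optional ngRNA. `predicted_efficiency` is the model's editing
efficiency in percent (here from models trained on a simulated screen,
so the numbers demonstrate the machinery, not wet-lab truth);
`rank` sorts designs per variant, ties broken deterministically. The
PAM-free control contig lands in `skipped.tsv` with reason
"no design found". The PE3b contig's winner carries `is_PE3b = 1`: its
ngRNA spacer only matches the edited sequence.

Training tables are tab-delimited (`group_id`, the 23 feature columns,
`efficiency` in percent); `pegrank train` fits a model with grouped
nested CV and writes a single-file JSON model, `pegrank explain`
reports mean-|SHAP| feature importance, `pegrank fold` prints D(i) for
one pegRNA, and `pegrank simulate` writes the synthetic fixtures.

VCF input needs a reference FASTA; alternatively a self-contained FASTA
dialect encodes the edit in the header:
`>myvariant|pos=201|ref=A|alt=ATT` followed by the window sequence.

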