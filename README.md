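# nichetraits

Trait-based analysis of microbial niche breadth. The package asks a
classic question of community data — are habitat generalists genomically
different from specialists? — and answers it with a reproducible chain of
analyses:

1. **Niche breadth** per taxon, from an occurrence matrix and an
   environmental table: each variable is min-max standardized to [0, 1],
   a taxon's range on a variable is the span of standardized values over
   the samples it occupies, and breadth is the mean range across
   variables. Single-occurrence taxa are excluded.
2. **Genome-derived traits**: completeness of metabolic modules (a module
   is steps of alternative KO sets, with `+` AND-complexes), binary
   module presence, and genome summaries (KO richness, genome size, GC,
   CDS count).
3. **Trait screen**: per-ecosystem binomial GLM (logit link, Wald test)
   of trait presence on breadth, a ≥2-ecosystem same-sign consensus
   filter, Benjamini–Hochberg adjustment, and a PERMANOVA of whole trait
   profiles against breadth as a continuous covariate.
4. **Life-history statistics**: average and Pielou-evenness mLHS (module
   completeness aggregated within life-history strategies), trait-space
   PCA with PC1 loadings, and Spearman–Ward–silhouette module clustering.
5. **Phylogenetic signal**: Blomberg's K with a permutation test on the
   variance of independent contrasts, plus a Mantel-style correlation of
   phylogenetic distance with breadth difference.

A bundled synthetic-data generator plants known generalist–specialist
structure (per-taxon environmental tolerance windows; module genes whose
prevalence rises or falls with true breadth), so every analysis can be
validated against ground truth.

## Worked example

Simulate a survey and recover the planted structure (all numbers below are
what these exact calls print):

```python
from scipy import stats
import pandas as pd
from nichetraits import niche_breadth, synthetic_data as sd

dataset = sd.simulate_dataset(seed=42, n_samples_per_ecosystem=60, n_taxa=120)
records = niche_breadth(dataset.occurrence, dataset.env, scope="global")
truth = pd.Series(dataset.truth.true_breadth)
shared = [t for t in records.index if t in truth.index]
rho = stats.spearmanr(records.loc[shared, "breadth"], truth.loc[shared])[0]
print(len(records), round(records["breadth"].median(), 3), round(rho, 3))
# 54 0.678 0.978
```

54 of 120 simulated taxa pass the two-sample occupancy filter; their
estimated breadth correlates with the generator's true breadth at
Spearman ρ = 0.978.

The trait screen on a larger draw (seed 42, 100 samples/ecosystem, 250
taxa; see `examples/04_trait_screen.py`) retains 7 of 55 modules by
two-ecosystem consensus — all of them planted-positive modules — and the
mLHS statistics on the same draw (`examples/05_life_history.py`) give:

```text
average mLHS vs breadth: r = 0.730, p = 3.4e-21
PC1 explains 10.6% of variance
module clustering: K = 2 (low confidence), best silhouette 0.090
```

Phylogenetic signal on a 64-tip tree with a Brownian trait
(`examples/06_phylo_signal.py`):

```text
Brownian trait on its own tree: K = 0.888, p = 0.001 (64 tips)
same values shuffled across tips: K = 0.000, p = 0.232
```

Each script in `examples/` is a short, self-contained narrative of one
capability; run them with `python examples/01_simulate_survey.py` etc.

## Command-line interface

The `nichetraits` command wraps the library for shell use:

```sh
nichetraits simulate --seed 42 --out run/          # synthetic survey + full analysis
nichetraits breadth --occurrence occ.tsv --env env.tsv --out breadth.tsv
nichetraits annotate-traits --annotations ko.tsv --catalog modules.tsv --out traits/
nichetraits screen --traits traits/module_binary.tsv --breadth breadth.tsv --out screen/
nichetraits permanova --traits traits/module_binary.tsv --breadth breadth.tsv
nichetraits lifehistory --completeness traits/completeness.tsv \
    --strategy-map strategy_map.tsv --breadth breadth.tsv --out lh/
nichetraits phylosignal --tree tree.nwk --breadth breadth.tsv --out signal.tsv
nichetraits run --config config.yaml --out run/    # full pipeline from YAML
```

All file formats are plain TSV (plus Newick trees and a tab-separated
module catalog `module_id<TAB>strategy<TAB>definition`, where a definition
is steps joined by `;`, alternatives by `|`, and AND-complex subunits by
`+`). See `docs/methods.md` for the model and every default.

## Layout

```
src/nichetraits/     library (io_formats, synthetic_data, niche_breadth,
                     genome_traits, trait_screen, life_history,
                     phylo_signal, pipeline, cli)
examples/            one narrative script per capability
tests/               unit + property + acceptance suites
scripts/acceptance.py  headline quantities of one full seeded run
docs/methods.md      model, defaults, numerical choices, limitations
```
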