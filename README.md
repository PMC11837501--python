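# magdiet

Genome-resolved functional profiling and diet-enrichment statistics for gut
metagenome-assembled genome (MAG) collections.

## The problem

Gut microbiomes break their host's diet down into usable compounds, and the
genomic potential for that work — which polysaccharides a community can
depolymerise, how it harvests energy, which vitamins it can synthesise — is
written in the gene content of its MAGs. `magdiet` takes the flat tables that
standard annotation tools emit (dbCAN-style CAZy family hits, KEGG Orthology
assignments, MEROPS peptidase families, HydDB-style hydrogenase groups,
CheckM-style completeness/contamination) and answers, reproducibly:

* which MAGs are **complete degraders** of cellulose, hemicellulose or chitin
  (every step of a hydrolysis chain encoded), which are **partial degraders**
  (at least one step but not all), and which can run energy pathways under
  the "at least 80 % of the enzymes" completeness rule;
* how substrate-degradation gene copies, **normalized to genome
  completeness** (`copies × 100 / completeness`), distribute across diet
  treatments — scaled PCA, one-way PERMANOVA, a homogeneity-of-dispersion
  permutation test, per-substrate Kruskal–Wallis with post-hoc Wilcoxon
  rank-sum tests, and fold changes of per-MAG group means;
* assembly-level community composition from single-copy marker (*rps3*)
  coverage shares, and per-treatment QC/novelty summaries (mean
  completeness/contamination, taxonomic class counts, MAGs inside a known
  species at ANI > 95).

The statistics are permutation-based and implemented here: pseudo-F from
partitioned sums of squared pairwise distances with a seeded label-shuffle
null (with exact enumeration for small designs), centroid distances in a
principal-coordinates embedding with negative-eigenvalue correction for the
dispersion test, and midrank/tie-corrected rank statistics with exact
small-sample Wilcoxon enumeration.

A first-class synthetic-data module generates diet-structured communities
(Bernoulli pathway-step presence, shifted-Poisson copy counts, uniform draft
completeness) with independently tallied ground-truth labels, so every stage
of the pipeline is testable without sequencing data.

## Worked example

The package ships a published collection of 43 gut MAGs from three reef fish
held on controlled diets (piscivorous hawkfish, herbivorous yellow tang,
invertivorous triggerfish):

```python
from magdiet import load_reef_fish_mags, qc_summary_by_group

records, design = load_reef_fish_mags()
for s in qc_summary_by_group(records, design.labels):
    d = s.as_display()
    print(d["group"], d["mean_completeness"], d["mean_contamination"],
          d["n_classes"], d["n_known_species"])
```

prints

```
piscivorous 91.44 4.47 4 9
herbivorous 94.19 3.63 7 3
invertivorous 89.99 3.3 5 1
```

i.e. each treatment's bins are high-quality drafts (~90–94 % complete, <5 %
contaminated), the herbivorous community spans the most taxonomic classes
(7), and only one invertivorous MAG falls inside a known species at
ANI > 95 — most of these genomes are novel.

`examples/` holds one narrative script per capability
(`qc_summary.py`, `classify_degraders.py`, `diet_statistics.py`,
`marker_community.py`); each builds or loads a small input, runs the method
and explains the numbers it prints. The same capabilities are exposed as a
thin CLI (`magdiet simulate|classify|profile|community|qc|stats|run-all`).

Pathway rules are data, not code: `src/magdiet/data/pathways/` holds the
default YAML definitions (hydrolysis chains, energy/fermentation pathways at
the 80 % rule, vitamin biosynthesis, hydrogenase group markers) and the
substrate-class family lists, both editable to match your annotation scheme.

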