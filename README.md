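# gutshift

Quantitative gut-content diet analysis for two-group fish cohorts — built
for studies of ontogenetic niche shift, where the question is whether
juvenile and mature (or small and large) individuals of one population
partition food resources.

The input is the standard product of a gut-content study: one CSV row per
fish with its maturity group, total length (cm), body mass (g), gut-content
mass (mg) and the biomass (mg) of every food category found in its gut,
plus a map assigning each category to a habitat guild — benthic (BE),
epiphytic (EP), epiphytic/benthic (EP/BE), planktonic (PL) or detritus (DE).
From that, `gutshift` computes the complete analysis chain used in trophic
ecology:

* **Diet importance** — frequency of occurrence %FO_i, biomass share %W_i
  (per-fish mean ± SD and CV, or group-pooled), gut fullness FC = 100 ·
  gut mass / body mass, and the Index of Relative Importance
  IRI_i = %FO_i × %W_i with %IRI_i = 100 · IRI_i / Σ IRI, for biomass-only
  data (no numeric prey counts).
* **Niche breadth** — richness S, Simpson dominance D = Σp², Levins
  B = 1/Σp², Shannon H′ = −Σp log p, and the standardised forms
  Ba = (B−1)/(S−1) and J′ = H′/log S, each with a delete-one-fish jackknife
  mean and SE, and a seeded label-permutation test of the between-group
  difference.
* **Diet overlap** — Schoener's α = 1 − ½Σ|p_ix − p_iy| and Horn's
  Ro = [Σ(p+q)log(p+q) − Σp log p − Σq log q]/(2 log 2), with jackknife SEs
  over the combined sample.
* **Community comparison** — Bray–Curtis dissimilarity between fish,
  one-way ANOSIM (Clarke's rank-based R with a seeded permutation p,
  exhaustively enumerated on small problems) and SIMPER decomposition of
  the average between-group dissimilarity into per-category contributions.
* **Ontogeny classification** — Ward minimum-variance clustering of guild
  profiles cut at two clusters and cross-tabulated against maturity, and
  two-group canonical discriminant analysis of arcsine-√ transformed guild
  percentages: eigenvalue λ₁, Wilks' Λ = 1/(1+λ₁), F on df (p, N−p−1),
  per-variable F-to-remove, structure correlations, and a resubstitution
  classification table.
* **Synthetic cohorts** — a calibrated generator (presence-thinned
  Dirichlet compositions × lognormal gut mass) reproducing the group mean
  compositions, occurrence frequencies, overdispersion and gut-mass moments
  of a published weatherfish (*Misgurnus fossilis*) study, whose group-level
  summary tables ship as packaged fixtures; it makes every downstream stage
  testable without access to raw field data.

## Worked example

Simulate a study-conditions cohort (33 juveniles + 26 mature, ~8% empty
guts) and run the full pipeline:

```
$ gutshift simulate --out cohort.csv --seed 42
wrote cohort.csv (59 fish, 6 empty) and cohort.spec.json

$ gutshift summarize cohort.csv --group juvenile | head -4
category             pct_w_mean  pct_w_sd  cv       pct_fo   iri      pct_iri
Copepoda             29.7055     24.1487   81.2938  86.6667  2574.48  34.1272
Asellus aquaticus    20.1662     22.4486   111.318  83.3333  1680.51  22.2768
Coleoptera larvae    10.272      18.3379   178.523  76.6667  787.521  10.4393

$ gutshift run --diet cohort.csv --out-dir report --n-perm 9999 --seed 42
diet summaries written for groups ['juvenile', 'mature']
ANOSIM R=0.310 p=0.0001 (9999 permutations)
DFA Wilks' lambda=0.397 F=14.28 correct=88.7%
wrote report/manifest.json (8 artifacts)
```

Reading the numbers: Copepoda dominates the simulated juvenile diet
(%IRI ≈ 34, driven by a high biomass share at high occurrence). ANOSIM
R = 0.31 with p = 1/10000 says juvenile and mature diets are weakly but
significantly separated in Bray–Curtis space — R near 0 would mean no
separation, near 1 complete separation. Wilks' Λ = 0.40 (F₅,₄₇ = 14.3)
confirms the separation on the five guild variables, with 88.7% of fish
re-classified into their own maturity group. The report directory also
holds the SIMPER table, niche/overlap table (Schoener α = 0.61, Horn
Ro = 0.76 here — substantial overlap despite the shift), cluster crosstab
and a JSON manifest with the seed and config hash; rerunning the same
config and seed reproduces every artifact byte-for-byte.

The same operations are available as a library (`gutshift.diet_summary`,
`gutshift.anosim`, `gutshift.overlap`, `gutshift.dfa_two_group`, ...),
operating on a validated `DietTable`.

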