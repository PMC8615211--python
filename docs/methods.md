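# Methods

This note documents the models and heuristics behind `mdartools`, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions.

## Classification model

A plant MDAR candidate is assigned to one targeting class from its
sequence features, in a fixed precedence order:

1. **Catalytic gate.** The residues essential for MDAR activity — the
   arginine and tyrosine at positions 320 and 349 of the rice MDAR
   reference — are located through the family alignment (the alignment
   column holding the reference residue is read out in the query; a gap
   counts as a deletion). Any substitution or deletion makes the sequence
   *MDAR-like* and stops classification. Rationale: without these residues
   the protein cannot be assumed to carry MDAR activity, so its targeting
   is moot.
2. **Class II (peroxisomal membrane).** A transmembrane span ending within
   the last 40 residues. A C-terminal TM is mechanically the least
   ambiguous signal, hence its precedence. If the span is not followed by
   a basic cluster (≥ 4 of {K,R} in 6 consecutive residues) the sequence
   is still class II but flagged `tm_no_basic_cluster` — a subclass seen
   in grasses whose localization is less certain.
3. **Class I (chloroplast/mitochondrion).** An N-terminal extension of at
   least 30 residues relative to a cytosolic-core reference row, scoring
   positive on the organellar heuristic, with no PTS1.
4. **Class III (cytosol/peroxisome).** Everything else. A PTS1-like
   tripeptide adds `dual_targeting_pts1`; its absence adds
   `cytosol_specific`. An organellar extension co-occurring with a PTS1 is
   genuinely contradictory and is kept as class III with a `conflict`
   flag rather than silently resolved.

When a phylogeny is supplied, each sequence also receives a `clade_class`:
the plurality class of the smallest surrounding clade with ≥ 3 leaves and
≥ 2 signal-classified (non-MDAR-like) members besides the query, walking
rootward from the leaf in the tree's rooted representation; ties leave it
unset. Disagreement adds `conflict` but never changes the class — signals
are primary, the tree corroborates.

## Feature detectors and defaults

| Parameter | Default | Meaning / rationale |
|---|---|---|
| PTS1 canonical | `SKL` | the textbook PTS1 tripeptide |
| PTS1 list | AKI, AKV, ASL, SNL, SKV, SKI, SKF, SRI, CKM, CKI | variants with experimental support on plant MDARs; the classifier uses canonical+listed only |
| PTS1 pattern tier | off | loose `[ASC][KRNS][LIVMF]`; off because the accepted tripeptides are enumerated, on for exploratory scans |
| TM window / threshold | 19 / 1.6 | classic Kyte–Doolittle settings for a single membrane span |
| C-terminal margin | 40 aa | a span must end this close to the C-terminus to count as an mPTS anchor |
| cluster window / min basic | 6 / 4 | `RRRRRW` (5 basics in 6) passes with margin; generalizes the archetype conservatively |
| cluster search tail | 10 aa after the span end | "immediately followed" |
| min extension | 30 aa | transit peptides are rarely shorter |
| organellar score | freq(S)+freq(R)−freq(D)−freq(E) > 0.05 over the first 50 aa | transit peptides are S/R-rich and acid-poor; a deliberately simple, replaceable composition heuristic (this package does not reimplement dedicated targeting predictors) |
| typical length | 400–552 aa | the observed range for single-core plant MDARs; outside it `atypical_length` |
| dual core | 2 motif hits ≥ 300 aa apart | proxy for two complete oxidoreductase domains without an HMM search |

Positions are 1-based inclusive throughout; `X` is tolerated as an unknown
residue (hydropathy 0, mismatches everything, never catalytic).

One detail of the mPTS scan is deliberate: TM spans are reported as the
union of full qualifying windows, so window smoothing extends the reported
span up to half a window past the physical TM terminus. The basic-cluster
search therefore begins half a window *before* the reported span end (and
runs to 10 residues after it); anchoring it strictly at the smoothed end
would systematically miss clusters that are genuinely adjacent to the
membrane span.

## Phylogeny

Distances are p-distances — mismatches over comparable columns, with
pairwise gap deletion — optionally Poisson-corrected (−ln(1−p)). Pairs
sharing fewer than 10 comparable columns are an error rather than a
guess. The tree is Saitou–Nei neighbor joining: join the pair minimizing
Q(i,j) = (m−2)d(i,j) − Σd(i,·) − Σd(j,·); pendant lengths by the standard
rate-corrected formula. Numerical conventions:

- negative pendant lengths are clamped to zero with the deficit moved to
  the sister branch, preserving the joined pair's path distance;
- all ties (in Q and in split hashing) break lexicographically on subtree
  labels, so output is identical across platforms and leaf orders;
- two taxa: the single distance splits equally across the two pendant
  edges (NJ is undefined at n = 2, a convention is required);
- the final three-taxon star uses the closed form, clamped at zero.

Bootstrap: columns are resampled with replacement to the original length,
the NJ tree is rebuilt, and each internal split of the *full-data* tree is
scored by its recurrence percentage (no consensus tree — supports annotate
the estimate, which matches how NJ trees are conventionally reported). A
replicate violating the comparable-columns minimum is redrawn (≤ 10
tries). Fixed seed ⇒ identical supports.

## Genetics

One or two unlinked loci with states +/+, +/−, −/−. Offspring
distributions come from Mendelian gamete frequencies, multiplied across
loci; lethal genotype classes are zeroed and survivors renormalized. The
chi-square goodness of fit uses E = p·N and df = k−1. The segregation
ratio is reported as second count over first (61, 78 → 1.28). Linked loci
and recombination are out of scope — the two-locus unlinked case is
exactly what the embryonic-lethality computation needs.

## Assay arithmetic

specific activity = |slope| / (ε · path) × V_reaction / (V_extract ·
c_protein), in µmol min⁻¹ mg⁻¹. ε defaults: 6.2 mM⁻¹cm⁻¹ (NADH, 340 nm,
falling) and 14 mM⁻¹cm⁻¹ (ascorbate, 265 nm, rising). A slope of the
wrong sign for the declared direction is rejected as a non-enzymatic
artifact. DHA = total − ASC with 0 ≤ ASC ≤ total enforced. Protein
determination and chromatogram processing are user inputs, not package
concerns.

## Synthetic families

The generator plants exactly the signals the detectors look for, on a
two-level lineage structure (ancestor → class ancestors → species copies)
so that classes form clades:

- ancestral core of 435 aa (configurable within 400–552), uniform residues
  with the catalytic R/Y fixed at 320/349;
- class decorations drawn once per class lineage and never mutated:
  a 60-aa S/R-rich extension (P(S)=P(R)=0.3) for class I, a 21-aa
  {I,L,V,F} span plus `RRRRRW` for class II (optionally the serine tail of
  the cluster-less grass subclass), a tripeptide uniform over the PTS1
  list for III_pts1, the bare core for III_cyto, and the core with R320→A
  for MDAR-like;
- divergence by seeded point substitutions at 0.05 per site per lineage
  step by default, sparing catalytic positions and planted signals;
- indel-free by construction, so the emitted alignment is exact: fixed
  blocks [extension | core | TM | cluster | PTS1], each row filling only
  its class's blocks, with an unmutated reference row `REF_CYTO`.

Ancestral cores are resampled wherever a 19-window mean hydropathy reaches
1.1 — a safety margin below the 1.6 detection threshold, so that two
rounds of 5% substitutions cannot push a core window over the TM cutoff
and create false positives.

Default family: 5 species × {1 I, 1 II, 1 III_pts1, 2 III_cyto}, seed 1 —
the Arabidopsis-like five-gene pattern repeated across species.

What this emulates: signal geometry, family structure, clade-consistent
divergence. What it does not: real MDAR residue composition, indels and
alignment error, splice variants, inter-species rate variation, weak or
degenerate signals. Passing tests therefore demonstrate that the detectors
and the pipeline logic are correct under known ground truth — not that the
heuristics match predictor-grade accuracy on real proteomes, where
extension boundaries and TM calls are noisier.

## Problem sizes

The default test and acceptance runs use the 26-sequence default family,
200 bootstrap replicates (the API default is 1000), 50 random additive
matrices of 4–6 taxa for the NJ oracle, 200 random sequences for the TM
brute-force comparison, and 1000 multinomial trials for the chi-square
calibration — sizes at which every property being tested is already
fully exercised.

## Known limitations

- The organellar heuristic is a composition score, not a trained
  predictor; on real data it should be swapped (it is a config entry) for
  a dedicated tool's output.
- Dual-core detection requires a user-supplied catalytic-context motif on
  real data; there is no HMM domain search.
- No tree rooting, consensus trees, or likelihood methods; the NJ tree is
  corroborative, not the primary classifier.
- Indel mode in the generator is intentionally unimplemented: with indels
  the true alignment is no longer known by construction, and alignment
  building is outside the package's scope.
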