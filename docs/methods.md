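# Methods

`gczone` reconstructs the dark-zone / light-zone (DZ/LZ) organization of a
germinal center (GC) from single-cell spatial expression and quantifies how
T-cell subtypes distribute across the DZ–LZ boundary. This note documents
the models, the defaults and the numerical choices, and what the synthetic
tissue used for testing does and does not emulate.

## Pipeline model

The pipeline assumes one pre-cropped GC per run: a cells × genes count
matrix with per-cell x/y positions in micrometers. Stages run in a fixed
order.

**QC.** Cells are retained when the number of detected genes is strictly
below 3,000 and the total count is strictly above 400. Both inequalities
are strict; ties are excluded.

**Normalization.** Counts are scaled per cell to the median library size,
`log1p`-transformed, and z-scaled per gene (sample SD, ddof = 1; constant
genes map to z = 0). The implementation is plain NumPy with a precisely
stated contract; the test suite verifies bit-level agreement with the
equivalent Scanpy pipeline (`normalize_total` → `log1p` → `scale`) as an
independent reference.

**Signature scoring.** The DZ (169-gene) and LZ (201-gene) spatial
signatures are scored per cell. The scoring algorithm is deliberately
pluggable because only the scores, not the scorer, are pinned down by the
segmentation rule:

- `mean_z` (default): mean of z-scaled expression over matched signature
  genes. Deterministic, order-invariant, and robust on small panels.
- `ctrl_bins`: Seurat/Scanpy-style module score — each signature gene is
  compared against `n_ctrl = 50` control genes drawn (seeded) from the same
  average-expression bin of `n_bins = 25` bins, on the log1p scale.

Gene matching is case-sensitive exact symbol matching; unmatched signature
genes are logged and skipped, with the matched fraction reported, since
panel and signature vocabularies generally differ.

**Classification.** The combined score is `dzlz = dz_score − lz_score`.
Cells with `dzlz > 0.3` are DZ, `dzlz < −0.3` are LZ, the rest are
intermediate (INT). The ±0.3 defaults are exposed as parameters because
their scale depends on the scoring method; with `mean_z` scores they sit
well inside the bimodal gap on polarized GCs.

**Region smoothing.** Cells are nodes of a radius graph (edge iff pairwise
Euclidean distance ≤ `neighbor_radius`, default 30 μm ≈ 2–3 cell
diameters). Synchronous (Jacobi) sweeps update all cells from the same
snapshot: INT cells take the majority phenotype among their DZ/LZ
neighbors; a DZ or LZ cell flips when the fraction of neighbors holding the
opposite phenotype strictly exceeds `dissimilar_fraction` (default 0.5).
Ties and neighbor-less cells keep their labels. Sweeps repeat until a
sweep changes nothing; the per-sweep change counts are recorded.
Synchronous updates make the result deterministic and independent of cell
order, at the price of possible period-2 oscillation; runs that have not
reached a fixpoint after `max_iter = 100` sweeps raise a hard
`ConvergenceError` rather than emitting an ill-defined segmentation. On
default synthetic GCs this affects roughly 1 seed in 25.

**Purity gate.** Each region must contain at least 70% of cells whose
*original* (pre-smoothing) phenotype matches the region. Measuring purity
against the original calls is the only reading under which the condition is
informative — post-smoothing labels would be pure by construction. Boundary
extraction refuses to run when the gate fails.

**Boundary and signed distance.** The boundary polyline consists of the
midpoints of all edges joining a DZ-region cell to an LZ-region cell,
ordered by projection onto the first principal axis of the midpoint cloud
(axis sign canonicalized, ties broken by edge order, hence deterministic).
Per-cell signed distance is the Euclidean distance to the nearest boundary
*vertex* — not the nearest polyline segment, a simplification that is exact
up to half the typical vertex spacing and much easier to verify — with the
sign taken from the region of the nearest region-labeled cell (DZ side
negative, LZ side positive; cells exactly on a vertex get 0).

## Spatial statistics

**Enrichment profile.** Cells are binned by signed distance from −100 μm
(DZ) to +100 μm (LZ) in 10-μm bins (half-open `[lo, hi)`, last bin closed
at +100). The per-bin mean of a 0/1 subtype indicator — i.e. the subtype
fraction — is the default "enrichment level"; a continuous per-cell score
is accepted as an alternative. An unweighted ordinary-least-squares line
through the non-empty bin means (enrichment per μm) summarizes the trend;
empty bins are excluded from the fit rather than imputed.

**Monte-Carlo envelope.** The null model reassigns the subtype label to a
uniformly random subset of the *observed* cell positions, keeping the
subtype count fixed — a label permutation that conditions on tissue
geometry rather than assuming uniform re-placement. Each of `n_sim`
replicates (default 10,000) yields a null slope; the 2.5th/97.5th
percentiles form the 95% envelope. Observed slope above the envelope →
"increasing" (toward the LZ), below → "decreasing", inside → "random".
The permutation loop is vectorized (random-key argpartition plus bincount),
so a 1,000-permutation envelope on 3,000 cells takes milliseconds.

Statistical power at this bin width and envelope level is governed by
`β·sqrt(k(1−p)·Σ(c−c̄)²/ (Σ(c−c̄)²·20/n)) ≈ β·57.7·sqrt(k(1−p))` for a
logistic gradient β and subtype size k, independently of the total cell
count. At k = 150 an enrichment doubling across the ±100 μm window
(β = ln 2/200 ≈ 0.0035/μm) sits near 2.4 null SDs, so the three-way call
detects it only in roughly two-thirds of replicates; reliable detection at
k = 150 needs a ≳2.2-fold change across the window.

**Nearest-neighbor exclusion test.** For point sets A (e.g. CD3+ T cells)
and B (e.g. AID+ DZ B cells), the observed statistic is each A point's
distance to its nearest B point. The null permutes the A/B labels over the
pooled observed positions (counts fixed) `n_rand` times and pools the
resulting distances. Observed and null samples are compared with a
two-sided Wilcoxon rank-sum test (exact enumeration for tie-free samples of
≤ 20, otherwise the normal approximation with continuity correction, via
`scipy.stats.mannwhitneyu`). "Excluded" means the observed median exceeds
the null median at p < α. ECDFs for plotting come from `scipy.stats.ecdf`.

## Synthetic tissue

The generator (`gczone.synthetic`) is the ground-truth source for every
downstream test. One simulated GC is:

- **Geometry** — `n_cells` (default 2,000) placed uniformly in a disc of
  radius 150 μm; a straight chord at angle `boundary_angle`, offset so the
  DZ side covers `dz_fraction` of the disc area (default 0.5), splits the
  disc. True zone = side of the chord.
- **Expression** — negative-binomial counts (dispersion 1.0 by default;
  var = μ + αμ²; α = 0 gives Poisson), per-gene baseline log-means drawn
  around `base_mean = 2` counts with SD 0.5. Signature genes (by default
  the packaged 169 + 201 signature symbols, plus 130 background genes) are
  shifted up by `signature_effect = 1.5` on the natural-log scale in their
  own zone. `label_noise = 0.1` flips the expression-generating zone of 10%
  of cells, emulating misclassified phenotypes; geometric truth is kept
  separately.
- **Subtypes** — each subtype gets exactly `n_cells` members with inclusion
  probability exactly `σ(α + β·s)` of signed distance s, where α is
  calibrated so the probabilities sum to the subtype size and the fixed-size
  draw uses systematic probability-proportional-to-size sampling. This
  makes the membership model *exactly* logistic, so a logistic regression
  of membership on signed distance is a consistent estimator of β
  (recovered within a few percent at n = 10,000). CSR control subtypes use
  uniform inclusion. Defaults: one LZ-enriched subtype ("Tfh",
  β = 0.02/μm, n = 150) and one CSR control ("naive_CD8", n = 150).

What the generator does **not** emulate: segmentation error, doublets,
platform-specific noise or sensitivity profiles, curved or multi-lobed
boundaries, 3-D tissue, and cell-type-dependent library sizes. Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not platform-level robustness
on real CosMx/Visium data.

The packaged signature file (`data/dz_lz_signature_synthetic.gmt`) is a
*synthetic stand-in* with the real set sizes (169 DZ-up, 201 LZ-up):
curated canonical GC marker symbols padded with placeholder names. It
drives simulation and testing and is not a substitute for the published
signature when annotating real tissue.

## Numerical and design choices

- Problem sizes in the test suite (2,000-cell GCs, 50 seeds for the purity
  contract, 200 datasets × 1,000 permutations for envelope calibration)
  were chosen so the whole suite runs in well under a minute per property
  on one CPU while keeping binomial noise comfortably inside the asserted
  bands.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs/manifests; stage seeds are derived from the run seed.
- Tertile bulk stratification breaks score ties by sample name so the
  grouping is invariant to input order; k-means (k = 3, fixed
  `random_state`) is the alternative rule.
- The chord offset for `dz_fraction ≠ 0.5` solves the circular-segment area
  equation by Brent's method; subtype calibration of α likewise.
- `ConvergenceError` rather than silent truncation on oscillation;
  `max_iter = 100` is far above the ~10 sweeps typical runs need.

## Known limitations

- Boundary extraction assumes a single roughly linear interface; GCs with
  fragmented or annular zonation would produce a poorly ordered polyline.
- Signed distance to the nearest vertex slightly overestimates distance
  where cross-edges are sparse.
- The exclusion test's label-permutation null conditions on the observed
  point union; it does not model inhomogeneous tissue-wide density changes.
- Multi-GC slides must be cropped upstream; the CLI processes one GC per
  invocation.

The bulk-cohort generator (`generate_bulk_cohort`) draws Gaussian
log-expression (SD 1) for the 370 signature genes plus 50 background genes
across `n_samples` (default 60), shifting DZ genes up and LZ genes down by
`effect` (default 1 SD) in a latent DZ-like class comprising 30% of samples
— below one third, so a tertile split can in principle capture the whole
class.
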