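# Methods

## Scoring model

For each case sample, each gene *n* is summarized by its case-to-normal
ratio `CNR_n = e_case / mean(e_controls)` on the linear scale, and each
pathway *p* by the activation strength

    PAS_p = Σ_n ARR_np · BTIF_n · lg(CNR_n)

summed over the pathway's member genes present in the data. The model's
assumptions are deliberately minimal: genes act additively and independently
within a pathway, a gene's influence is fully described by its fixed
activator/repressor role weight `ARR ∈ {−1, −0.5, 0, 0.5, 1}`, and pathway
topology (the gene's position in the cascade) is ignored. Genes whose
expression is statistically indistinguishable from the control distribution
are excluded from the sum by the flag `BTIF`, so PAS aggregates only
significantly perturbed members.

### Tolerance interval (BTIF)

`BTIF_n = 1` when the case's log10 expression falls outside the control
tolerance interval `μ_n ± z·σ_n`, with `μ_n`, `σ_n` the mean and sample
standard deviation (ddof = 1) of log10 control expression for gene *n*, and
`z = 1.96` delimiting the two-sided p > 0.05 band under a normal
approximation. Notes on this choice:

* The flag's definition is stated here in the direction its name implies:
  1 = beyond the interval = significantly perturbed, 0 = essentially normal.
  The role weight ARR is a multiplier in the sum, not part of the flagging
  criterion.
* The normal approximation with the sample sd is crude for small control
  groups (4 controls give a noisy σ̂ and an inflated effective flag rate),
  but it is deterministic and transparent. `z_threshold` is configurable.
* With a single control sample the interval is undefined; the scorer then
  refuses unless `btif_all_on` mode is selected, which sets every flag to 1
  (useful for single-control designs and for sensitivity analysis).
* If `σ_n = 0` (constant controls), the gene is flagged iff the case value
  differs from the constant.
* An optional fold-change gate `|lg CNR| ≥ lg(min_fold)` can be layered on
  top; the default `min_fold = 1` disables it, so the statistical criterion
  alone decides.

### Control average and floor

The CNR denominator uses the arithmetic mean of control expression on the
linear scale (a geometric alternative is available via
`control_average="geometric"`). Both numerator and denominator are floored
at `1e-6 ×` the matrix-wide median of nonzero values (configurable as an
absolute floor), which keeps ratios and logarithms finite for sequencing
dropouts. The floor is applied after averaging the controls. Flooring at a
value this far below signal means a dropout zero produces a large negative
lg CNR — a deliberate property: dropout noise is visible at the gene level
and is what the pathway sum has to absorb.

## Expression handling

* **Probe aggregation.** Duplicate gene rows (multiple probes per gene) are
  collapsed by arithmetic mean on the linear scale before normalization —
  the least surprising default; alias resolution of gene symbols is out of
  scope and must happen upstream.
* **Quantile normalization** forces every sample's value distribution onto
  the across-sample mean of per-rank values (sort / average / re-map),
  preserving within-sample ranks. Tied values receive the mean of the
  reference entries their sorted positions span — deterministic and
  symmetric. On tie-free data the transform is idempotent and equalizes
  column means to ~1e-15. It is exposed as a scikit-learn transformer
  (`QuantileNormalizer`, samples as rows) whose fitted reference can be
  frozen and applied to new samples.
* **Normalization policy.** Microarray-style data are quantile normalized by
  default; matrices whose platform label contains `seq`/`ngs` are passed
  through unchanged, since count data normalization is a separate topic and
  the scoring operates on within-platform ratios anyway. Both behaviours can
  be forced.
* Gene symbols are canonicalized by trim + uppercase everywhere; one gene
  may carry different ARR values in different pathways (roles are stored per
  (pathway, gene) pair).

## Concordance analysis

For samples profiled on two platforms, the per-sample Pearson correlation is
computed between the platforms' per-gene lg CNR vectors (transcriptome
level) and between their per-pathway PAS vectors (signalome level), each
platform scored against its own controls on the intersected gene set.
Pearson is the default estimator because the compared quantities are the
plotted values themselves; Spearman is available behind a flag. An
`averaged` row correlates the across-replicate *mean profiles* (not the mean
of per-sample correlations — with few replicates the mean profile is the
better-determined object, and both interpretations are computable from the
per-sample tables). Correlations are reported as signed r (r² optional in
downstream use); a constant vector yields NaN rather than an arbitrary
number. Pairwise-incomplete genes are dropped before correlating.

## Synthetic two-platform generator

One latent log10 expression value exists per gene and sample:
`latent = base_gene + biological noise`, with case samples additionally
shifted by `delta · direction_p · sign(ARR)` for members of perturbed
pathways (so an activated pathway has activators up and repressors down, and
its true PAS is positive). Each platform observes

    observed = 10^(latent + bias_gene,platform + ε),  ε ~ N(0, σ_platform)

then zeroes the value with probability `dropout_rate`. All noise is
log-additive on the log10 scale, matching the algorithm's lg-space
arithmetic; in the noise-free limit the gene × platform bias cancels
*exactly* in the CNR (the bias multiplies case and control alike), which the
tests verify to 1e-9.

Defaults (the `heavy_noise_regime` preset):

| parameter | default | meaning |
|---|---|---|
| n_pathways × genes_per_pathway | 90 × 30 | scale of a curated signaling knowledge base |
| activator_fraction | 0.7 | activator-heavy membership, ARR ±1 (partial roles optional) |
| n_case / n_control | 4 / 4 | treated-vs-untreated cell-line design |
| perturbed_fraction | 0.3 | fraction of pathways truly responding, random direction |
| delta | 0.5 | log10 effect size (≈3-fold) on perturbed members |
| sigma_bio | 0.3 | biological sample-to-sample sd (log10), shared by platforms |
| sigma_platform | 1.0 / 0.8 | per-measurement noise sd (log10) per platform |
| bias_sd | 0.5 | sd of the fixed gene×platform offset |
| dropout_rate | 0.1 / 0.02 | zero-observation probability per platform |
| base_mean / base_sd | 2.0 / 0.7 | baseline log10 expression distribution |

Pathway membership in fixtures is disjoint, keeping expected scores
analytically transparent; real pathway collections overlap heavily, so
cross-pathway correlations of real PAS profiles are understated here. The
generator models neither read-level sequencing artifacts nor array probe
chemistry — platform error is a single Gaussian per measurement plus
dropout. Consequently, passing tests demonstrate the *mechanism* (bias
cancellation, error averaging by summation) rather than calibrated agreement
with any specific instrument pair.

Under these defaults the gene-level cross-platform correlation is ≈0.05–0.1
and the pathway-level correlation ≈0.15–0.3. The per-measurement noise
(sd 1.0 log10 units ≈ a 10-fold error) is deliberately harsh; at this level
the tolerance-interval gate admits mostly noise-driven genes carrying
|lg CNR| ≈ 2 each, which caps how high the 30-gene pathway sum's
cross-platform correlation can climb. The phenomenon of interest is the
*contrast* — pathway-level correlation exceeds gene-level correlation in
≥95% of seeded replicates, and the gap grows monotonically as pathways pool
more genes (5 → 20 → 80) — and that is what the acceptance checks assert.

All randomness flows through fixed seeded streams (`numpy` Generator seeded
by `[seed, stream]`), so every output is reproducible bit-for-bit from the
configuration.

## Numerical and interface choices

* lg CNR is stored alongside CNR and is exactly `log10(cnr)`.
* PAS is evaluated as a weight-matrix product; it agrees with a naive
  triple loop to 1e-12 and is linear in membership, invariant under gene and
  member reordering.
* Pathway-db files render ARR with one decimal place and expression files
  render values with `repr`, making write → read → write byte-stable.
* Test and acceptance problem sizes: 20 simulation replicates per condition
  and pathway sizes {5, 20, 80} for the scaling checks — enough for stable
  means at ~10 s of compute.
* CLI exit codes follow click conventions: 2 for usage errors, 1 for
  data/runtime errors. Numeric CLI output uses 6 significant digits by
  default (`--precision` for more).
* Control samples are not themselves scored (no leave-one-out CNR); only
  designated case samples receive scores.

## Known limitations

* The normal tolerance interval is anti-conservative for < 5 controls.
* Quantile normalization of heavily zero-inflated data maps dropout zeros to
  small tie-averaged positives, which dampens but does not remove their
  effect on CNR.
* PAS values are comparable across samples scored against the same controls
  and pathway set, but have no absolute scale across pathway databases.
* The concordance analysis assumes the two platforms share sample ids (or an
  explicit pairing file); no attempt is made to match samples by profile
  similarity.
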