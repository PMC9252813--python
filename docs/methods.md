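# Methods

This note documents the models, conventions and numerical choices behind
`ms2ident`, and what the synthetic-data experiments do and do not show.

## Spectrum model

A spectrum is a centroided peak list with precursor metadata. On
construction, peaks are sorted by m/z, neighbours closer than the merge
tolerance (default **0.001 Da**, configurable) are merged with
intensity-weighted m/z and summed intensities, and intensities are rescaled
to relative percent of the base peak (base = exactly 100; the scaling is
computed as `100·(i/top)` so the base peak is bit-exact). Normalization is
idempotent and scale-invariant. Noise removal drops peaks below a relative
intensity threshold (default **0.1 %**) and renormalizes; the base peak
always survives. Collision energies are restricted to the 10/20/40 eV
levels typical of ESI-QTOF acquisition protocols, or unknown.

Supported formats: plain two-column peak lists with `# key: value`
directives, NIST-style MSP (strict `Num Peaks` consistency check; unknown
header keys preserved verbatim), and MGF via pyteomics. Peak values are
printed with six decimals (m/z) and four (intensity), and round-trips are
exact at that precision.

## Mass and formula conventions

Element masses are the most-abundant-isotope masses from the NIST table
shipped with pyteomics. All ions are treated as singly charged and
even-electron. Adduct shifts use the proton-mass convention
(+/−1.007276 Da; electron mass ignored — an error < 0.003 Da/z·10⁻³, i.e.
well under 1 ppm at metabolite masses). The built-in table covers [M+H]+,
[M+Na]+, [M+NH4]+, [M−H]−, [M+Cl]−, [M+FA−H]− and can be extended through a
plain-text config file (`label polarity shift` rows).

Non-protonated adducts follow the *precursor-only* rule: daughter ions are
always computed as protonated/deprotonated species, and only the intact
precursor ion carries the full adduct shift. This reflects the physics of
most ESI adducts (the charge carrier is usually lost or transferred on
fragmentation; rare exceptions such as sodiated acylglycerol fragments are
out of scope).

`decompose_mass` enumerates formulas over C, H, N, O, P, S and halogens
within a ppm window of a neutral target mass. Heavy elements are searched
depth-first (heaviest first) with mass pruning; the hydrogen count is then
solved directly from the residual mass, so the state space is the product of
heavy-element ranges only (guarded at 10⁷ states). Candidates must have
ring-plus-double-bond equivalents `RDBE = 1 + Σ nᵢ(vᵢ−2)/2 ≥ 0` and integer
(standard valences C4, H1, N3, O2, P5, S6, halogens 1 — the consistency
condition for neutral even-electron species). Output is sorted by absolute
mass error with a lexicographic tie-break.

## Fragmenter

Fragment enumeration is purely combinatorial (no learned fragmentation
probabilities): candidate fragments are the connected components left after
deleting any subset of at most `max_depth` breakable bonds, where a bond is
breakable if it is a single bond or lies in a ring. Each bond cut costs one
depth unit, so splitting a ring requires two cuts — a single ring-bond cut
leaves the molecule connected and only contributes ring-opened variants of
the intact composition. Each fragment is emitted with hydrogen shifts of
−2…+2 H (the common rearrangement allowance), deduplicated by
(formula, h_shift) keeping the fewest broken bonds, which also makes the
fragment set monotone in depth. Default `max_depth` is **2**, balancing
coverage against the `O(bonds^depth)` subset enumeration for typical
metabolite sizes (≤ ~35 heavy atoms).

Peak assignment picks, per peak, the fragment ion of smallest |ppm error|
within tolerance (default **10 ppm**), breaking ties by fewer broken bonds,
then smaller |h_shift|, then substructure SMILES — fully deterministic. If
the spectrum's adduct is known, the intact adduct ion participates as a
candidate for the precursor peak (the only place a non-protonated adduct
shift appears, per the precursor-only rule).

## Peak matching and similarity scores

Two spectra are matched one-to-one among peak pairs within
`max(tol_ppm·mz·10⁻⁶, tol_abs)`; the absolute floor (default **0.001 Da**)
prevents vanishing windows at low m/z, and the ppm window is evaluated at
the smaller of the two m/z values so matching is symmetric. The pairing is
the assignment with maximum pair count and, among those, minimum total
|Δm/z| (Hungarian algorithm, `scipy.optimize.linear_sum_assignment` with a
large penalty for out-of-tolerance cells). A greedy
smallest-difference-first pass gives the same result on well-separated
peaks, but in chained near-tolerance configurations greedy can drop a pair
(A = {10, 11}, B = {11, 11.9}, tol 1 Da: greedy pairs 11–11 and stops at one
pair; the optimum pairs 10–11 and 11–11.9); the optimal assignment is also
symmetric in its arguments and agrees exactly with exhaustive enumeration,
which is why it is used.

The Dice score is count-based (intensity-agnostic): `2m/(|A|+|B|)` for `m`
matched pairs. The dot-product score is the cosine of weight vectors
`w = mz^p · intensity^q` with default exponents **p = q = 0.5** (classic
library-search weighting; both configurable), where the numerator runs over
matched pairs and the denominator over all peaks, so unmatched peaks dilute
the score. Both are symmetric and bounded in [0, 1].

Multi-energy queries are scored as the **mean of per-energy scores over the
energies present in the query**, with energies missing from the candidate
contributing zero. How scores should be aggregated across collision
energies is genuinely open; the mean is chosen because it keeps the score in
[0, 1], rewards libraries that cover all the query's energies, and reduces
to the single-energy score for single-spectrum queries.

## Identification and evaluation

`identify` retrieves candidates via a bisect index on neutral monoisotopic
mass (verified identical to a linear scan), scores each with the selected
similarity, and ranks descending with ties broken by candidate identifier —
output is fully deterministic. Defaults: candidate mass tolerance 10 ppm,
top 10 hits. An empty retrieval window yields a `no-candidates` status, not
an exception.

`evaluate` reports the fraction of queries whose true compound ranks 1,
≤ 5 and ≤ 10, and the fraction whose top hit has the correct molecular
formula. The true compound's rank under score ties is **pessimistic**: all
tied candidates count ahead of it, so reported rank-1 means uniquely best.
A query whose true compound falls outside the mass window counts as a miss
at every cutoff. Because a uniquely-best true structure necessarily has the
true formula, formula accuracy ≥ rank-1 accuracy by construction.

## Neutral-loss search

The neutral-loss spectrum keeps one loss `precursor m/z − peak m/z` per
product peak with loss ≥ **0.5 Da** (dropping the precursor's own ≈0 loss),
inherits intensities, and renormalizes. Matching between loss spectra uses
an **absolute tolerance of 0.01 Da**: losses are differences of two measured
masses, so a ppm window tied to the (small) loss value would be
meaningless. The search scores every library record — no precursor-mass
filter, since analogs with shifted parent masses are exactly the intended
matches — by mean per-energy Dice over neutral-loss spectra, and is
restricted to Dice because count overlap of characteristic losses, not
intensity agreement, is the analog signal.

## Synthetic library generator

The generator emulates a per-energy in-silico spectral library over 147
packaged, curated real structures (metabolites, natural products,
xenobiotics; all neutral, < 520 Da, pairwise-distinct molecular formulas so
simulated libraries contain no exact-mass ties). For each compound it
enumerates fragments at depth 2 and draws up to 8 fragment peaks per energy
with probability ∝ exp(−m/z / τ), with τ = 400/180/80 Da at 10/20/40 eV, and
adds the precursor ion at relative intensity 100/40/8 — reproducing the
qualitative CID behaviour that higher collision energy depletes the
precursor and shifts intensity toward low-mass fragments. Fragment
intensities are uniform on [5, 100] before normalization.

Queries are noised copies of the library spectra: Gaussian m/z jitter
(default **2 ppm** s.d., the accuracy class of a well-calibrated QTOF) plus
uniformly placed spurious peaks (default **2** per spectrum, intensities
uniform on [0.5, 20] %). All draws flow from one `numpy` Generator seeded by
a single integer, so libraries are byte-reproducible.

What the simulation does *not* model: intensity variation between replicate
acquisitions, correlated chemical noise and co-isolated contaminants,
isotope peaks, multiply charged ions, instrument-specific fragmentation
propensities, and any relationship between true fragmentation chemistry and
the uniform intensity draws. Passing benchmarks on this generator therefore
demonstrates the correctness and internal consistency of the search
machinery — retrieval, scoring, ranking, neutral-loss invariance — not
identification accuracy on real experimental spectra, which is dominated by
how well library spectra resemble measured ones.

## Experiment sizes and numerical checks

The packaged experiments use library sizes of 15–50 compounds, 200 random
spectrum pairs for score-oracle agreement (peak counts ≤ 6 so the exhaustive
matching oracle stays tractable), 100 random formulas for decomposition
containment, and 10 replicates for the noise-degradation curve; these sizes
give stable results in seconds on one CPU. The degradation experiment
widens the candidate mass window to 20 % so several candidates compete per
query (with the realistic 10 ppm window the distinct-formula library almost
always yields a single candidate and rank-1 accuracy is trivially flat).
Score and mass identities are asserted to 1e-9; floating-point equality is
claimed only where the arithmetic is exact by construction.

## Known limitations

- The fragmenter is an independent combinatorial scheme: it annotates peaks
  with *plausible* compositions, not mechanistically ranked structures, and
  hydrogen shifts beyond ±2 are not considered.
- Dice is intensity-agnostic by design; a metadata-boosted score is not
  implemented.
- Only singly charged, even-electron ions; no isotope-pattern scoring;
  no EI spectra; no retention-time dimension.
- MSP support targets the NIST dialect written by this package plus common
  key synonyms; exotic vendor dialects may need pre-conversion.
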