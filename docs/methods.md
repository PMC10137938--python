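# Methods

## Scope and data flow

`acepep` covers the statistical and thermodynamic analysis layer of an
exhaustive ACE-tetrapeptide virtual screen. Structure preparation, docking,
scoring functions, MD propagation, GB polar solvation and SASA evaluation
are upstream engines whose *outputs* this package consumes as plain-text
tables; it never recomputes them from coordinates. The synthetic-data module
generates inputs with the statistical structure each stage assumes, so the
pipeline can be exercised and validated without those engines.

## Sequence space and property encoding

The library is all 20⁴ = 160,000 linear tetrapeptides over the canonical
alphabet `ACDEFGHIKLMNPQRSTVWY`, enumerated lexicographically (`AAAA` …
`YYYY`). The design is perfectly balanced: every residue occurs exactly
8,000 times at each position, which is what lets slice frequencies and the
marginal-effect recovery checks work without reweighting.

The default residue-property scheme classes are aromatic {F,W,Y,H},
positive {R,K,H}, negative {D,E}, polar {S,T,N,Q,C}, aliphatic
{A,V,L,I,M,P,G} and small {G,A,S,C,T}; a residue may carry several classes
(His is aromatic *and* basic). These are exactly the categories in which
ACE-binding preference manifests — aromatic stacking, salt-bridge-capable
basic residues, and short side chains that fail to anchor in the pocket.
The scheme is a YAML file and fully substitutable. Transactions are
positional (`P1:aromatic`) by default; a bag-of-properties encoding is
available via a flag because either convention is defensible for rule
mining — positional encoding was chosen as the default since the screen's
central finding is position-specific.

## Ranked-library statistics

Peptides are ranked ascending by docking score (more negative = stronger
predicted binding), ties broken lexicographically so ranking is total and
deterministic even at the slice boundary. Positional frequency tables for
the top-N/bottom-N slices (N = 5,000 by default) report percentages that sum
to 100 per column. Enrichment between slices is a log2 ratio of counts with
a 0.5 pseudo-count per cell so residues absent from one slice stay finite.

## Association-rule mining

FP-growth is implemented in-package (a prefix tree ordered by item
frequency, mined recursively through conditional pattern bases) with
support = occurrence/N and confidence = Sup(X∪Y)/Sup(X). Correctness is
guaranteed by test, not by construction alone: on random databases with ≤ 12
distinct items the output must be identical to an exhaustive
subset-enumeration oracle (a bitmask zeta transform). Defaults
min_support = 0.05 and min_confidence = 0.6 are conventional screening
values; consequents are single items by default, the standard practice that
keeps rule lists interpretable. Lift/leverage metrics are intentionally out
of scope.

## MM/GBSA + interaction entropy

Constants: k = 0.0019872 kcal·mol⁻¹·K⁻¹, T = 300 K by default (the
production-run temperature). ΔG_np = γ·SASA + β with γ = 0.005
kcal·mol⁻¹·Å⁻², β = 0; the module applies this to whatever SASA (difference)
it is given.

Enthalpy components are arithmetic means over an evenly strided subsample of
100 frames; the IE exponential average uses up to 10,000 frames. The split
exists because the exponential average is dominated by the largest
fluctuations and converges roughly two orders of magnitude more slowly than
the component means. IE is evaluated as kT·(logsumexp(ΔE/kT) − ln n): the
max-shifted log-sum-exp is mandatory because βΔE of a few kcal/mol already
overflows a double under naive exponentiation. IE is non-negative by
Jensen's inequality; a constant series returns exactly 0 by an explicit
zero-fluctuation branch (floating-point subtraction of the mean would
otherwise leave ~1e-14 residue).

Finite-sample behaviour: for Gaussian ΔE the estimator converges to
σ²/(2kT) with a downward bias at small n that decays like n^{-1/2}; the
million-sample check in the acceptance suite sits within 1 % of the closed
form, while the 10,000-frame defaults land visibly below it. This is a
property of the estimator, not a bug, and is why reported −TΔS values from
short series should be read as lower-biased.

The bundled reference table of twelve ACE–tetrapeptide complexes is used as
a worked-example input. Reassembling each row (ΔH from components, ΔG_bind
= ΔH + (−TΔS)) reproduces the printed values within ±0.02 kcal/mol —
two-decimal rounding — for eleven rows; the ACE-RWWD row is internally
inconsistent by ~0.1 kcal/mol and is carried verbatim with a documented
wider tolerance rather than "corrected".

## Alanine scanning and hotspots

Per-residue contributions ΔΔG^{x→a} = ΔG^x − ΔG^a come from upstream mutant
runs (default 3 replicas, reported mean ± SD). Favourable contributions are
negative, so the hotspot threshold "more than 1 kcal/mol" is applied as
mean ≤ −1 kcal/mol. Occurrence is counted over complexes by default —
a residue passing in 5 of 10 complexes has occurrence 0.5 and is a
recurrent hotspot at the 50 % cutoff — with a flag to count over pooled
replicas instead, since either denominator is a reasonable reading.
Hotspot calling is monotone in the threshold and invariant to complex
relabelling; all complexes must share a residue universe.

## Dose–response fitting

Inhibition = ((b−c)−(a−c))/(b−c)×100 from hippuric-acid peak areas; it is
invariant to common rescaling of all areas. IC50s come from a
four-parameter log-logistic fit y = bottom + (top−bottom)/(1+10^{h(logIC50 −
log x)}), parametrised in log10(IC50) for optimizer stability, starting at
bottom = 0, top = 100, IC50 = geometric mean of the concentrations, slope 1,
with bottom and top constrained to [0, 100] % by default (the standard
constrained family for enzyme-inhibition assays). The 95 % CI half-width on
IC50 uses the delta method from the covariance of log10(IC50). A fit is
declared non-converged — IC50 reported as NaN, never a number — when the
optimizer fails, the covariance is singular, the fitted amplitude is under
1 percentage point, or the observed response spans less than 5 percentage
points (a flat series carries no IC50 information).

A unit note: tetrapeptide stocks quoted as "2 mg/L" are only a few μM for a
~600–700 Da peptide and therefore cannot span tens-of-μM IC50s; `molar_mass`
and `mg_per_l_to_um` are provided so users can audit such conversions. The
package treats concentrations as μM throughout.

## Synthetic-data generators

All generators are deterministic per seed (`numpy.random.default_rng`).

*Score landscape*: score = baseline + Σ_position effect(residue, position) +
Gaussian noise, then an order-preserving affine calibration onto the
published score range −12.125 … −1.536. Default effects (chosen once, per
position): W −1.2, Y and F −0.7, R −0.6, H −0.5 kcal-like units favourable;
short-side-chain residues {I,V,A,T,C,L,P,G,S} +0.4; others 0; noise SD 0.5.
These magnitudes make Trp modal at all four positions of the top-5000 slice
with other aromatics/basics enriched and small residues depleted — the
qualitative pattern of the real screen — while the noise keeps the slice
composition stochastic. The additive model is the simplest that reproduces
positional enrichment; it deliberately contains no pairwise terms and no
claim of emulating docking physics, so tests passing on it say nothing
about real docking scores beyond the pipeline arithmetic being right.

*Energy series*: Gaussian per-frame components around configured means
(defaults mimic a strong binder), optional AR(1) autocorrelation (MD frames
are autocorrelated; default φ = 0) with innovation variance scaled to keep
the marginal SD fixed.

*Alanine tables*: planted hotspot residues receive means ≤ −1.3 kcal/mol in
at least the configured fraction of complexes, all others stay in
(−0.5, 0.2); replica noise is double-centred so per-residue means and
per-replica totals are exact, making decomposition conservation hold to
machine precision by construction. When a per-complex total is requested the
residual is absorbed by passing residues (if favourable) or non-passing
residues (if unfavourable), with feasibility checks that refuse
configurations that would create or destroy hotspots.

*Dose–response*: 7-point 2× serial dilution centred on the true IC50 (the
dilution factor is a package choice; only the 7-gradient design is given),
Gaussian noise on inhibition, clipped to the plausible [−9.9, 109.9] %
window.

## Problem sizes and determinism

The test and acceptance runs use the full 160,000-peptide library for
ranking stages, 10⁶ samples for the IE closed-form check, 50 random
databases for the mining oracle, 10 complexes × 3 replicas for alanine
scans, and 100 replicate curves for IC50 recovery — sizes chosen to make
the statistical checks sharp while keeping the whole suite fast on one
core. Every stochastic test is seeded; hypothesis runs derandomised.

## Known limitations

- The synthetic landscape cannot reproduce the published Fig-1 percentages
  or score list; those derive from a proprietary docking engine and are
  bundled only as qualitative anchors.
- IE from 10⁴ frames is biased low for large fluctuation amplitudes
  (σ ≳ 3 kcal/mol at 300 K); report it with that caveat.
- Whether published entropy values pooled the three MD replicas is
  unspecified upstream; the model fits whatever series it is handed.
- The 5 Å residue-selection step of alanine scanning needs structures and
  is out of scope; the scanned residue list is an input.
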