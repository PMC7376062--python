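# Methods

This note records the models implemented in `follisim`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Reticular network representation and topology metrics

A follicular stromal network is an undirected spatial graph: nodes are
CXCL13⁺ stromal cells with 3D positions (µm) and a subtype label (CD21/35⁺
FDC or CD21⁻ RC), edges are physical connections between neighbouring cells.

Metrics follow the standard definitions. The mean local clustering
coefficient C_local averages 2·T(v)/(deg(v)(deg(v)−1)) over nodes, with
degree-0/1 nodes contributing 0 (a convention choice — they have no defined
triangle fraction; including them as 0 keeps the mean comparable across
densities). Transitivity C_global is 3·triangles / connected triples. The
mean shortest path length L averages hop counts over all distinct reachable
ordered pairs of the largest connected component; self-pairs are excluded.
That convention is the one that reproduces the reported random-graph reference value
(G(198, 1163) gives L ≈ 2.41), so it is the default; the component coverage
fraction is reported for disconnected graphs.

Small-world indices use an Erdős–Rényi G(n, m) null with matched node and
edge counts (fixed edge count rather than G(n, p), so the null matches the
measured network exactly) averaged over seeded realizations, and a ring lattice at the
matched mean degree rounded down to even, whose clustering has the closed
form 3(k−2)/(4(k−1)). σ = (C/C_rand)/(L/L_rand) exceeds 1 for small-world
graphs; ω = L_rand/L − C/C_latt is near 0 for small worlds, positive for
random-like and negative for lattice-like graphs.

The FDC-vs-RC comparison uses a two-sided Mann–Whitney U test per metric
(degree, incident edge length). A rank-based test is appropriate for a
single network's skewed per-node distributions; the original study compared
binned distributions across animals with a two-way ANOVA, which has no
per-network analogue.

## Follicle network generator

Geometry is a slab mirroring the imaged tissue volumes: a disc of radius R
in xy, 35 µm thick in z. FDCs (45% of nodes by default) are uniform in a
central core disc of radius 0.55·R; RCs fill the outer annulus, with 35% of
them packed into a 25 µm subcapsular rim band. Node pairs within
`connect_radius` are wired with probability exp(−d/`connect_decay`), and a
fraction `shortcut_fraction` of the local edge count is added as random
long-range edges (the measured network's occasional long connections between
cliques).

Defaults were calibrated numerically against the measured follicle
statistics (198 nodes, 1163 edges, C_local 0.60, C_global 0.57, L 4.17):
R = 136 µm, connect_radius = 38 µm, connect_decay = 400 µm,
shortcut_fraction = 0.004. Two findings from that calibration are worth
recording. First, a strongly distance-decaying kernel cannot reach the
measured clustering — random thinning removes triangles faster than triples,
capping C near 0.3 — so the calibrated kernel is nearly hard-radius
(decay ≫ radius), which recovers the random-geometric-graph clustering level
(≈0.59 in a thin slab) that matches the tissue. Second, the dense FDC core
raises clustering slightly above the homogeneous-density value, which is why
the calibrated radius is what it is. The calibration surface is statistical:
the generator makes no claim to reproduce any particular follicle's wiring,
only the family statistics. `calibrate_generator` re-runs this fit for other
targets with random search (log-uniform over the decay scale) plus local
jitter refinement; 20 seeds per candidate average out realization noise.

Degenerate parameter sets that disconnect the majority of nodes raise a
synthesis failure rather than returning a fragmented network.

## Chemokine field

The soluble pool obeys ∂c/∂t = D∇²c + s(x) − λc − k_on·c + k_off·b on a
regular lattice (default spacing 5 µm for production runs, 8 µm in the
desk-scale experiments; both resolve the ~15–50 µm gradient length scales);
the immobilized pool b does not diffuse and obeys ∂b/∂t = k_on·c − k_off·b −
λ_i·b with λ_i = λ unless overridden. Secretion is deposited into each
stromal cell's nearest voxel, subtype-specific. Boundaries are reflective by
default (the follicle treated as a closed domain); an absorbing option
models sinks at the follicle edge.

Time stepping is forward-time central-space with a combined
positivity/stability guard dt ≤ 1/(6D/h² + λ + k_on); violating steps are
refused with a suggested dt. Because the system is linear, the steady state
is also solved exactly: substituting the immobilized balance
b = k_on·c/(k_off + λ_i) turns the soluble equation into a screened Poisson
problem with effective decay λ_eff = λ + k_on·λ_i/(k_off + λ_i), solved by
conjugate gradients (the operator is symmetric positive definite;
rtol 1e−12, sparse-LU fallback). The two routes agree in tests to 0.1%.

Model parameterizations: model 1 (ECM-constrained) uses D = 0.19 µm² s⁻¹,
the measured single-molecule median in untreated tissue, with λ chosen so
the screening length √(D/λ) is 15 µm — a module default, not a measured
value. Model 2 (freely soluble) uses D = 1.6 µm² s⁻¹ (the
heparinase-treated median) with λ = 5×10⁻⁵ s⁻¹, putting the screening
length beyond the follicle radius and hence producing a near-homogeneous
field. Secretion is rescaled so both steady states carry the same total
chemokine mass; comparisons between the models are therefore about spatial
arrangement, not amount. The explicit two-pool immobilization model is
available but off by default in the model comparison — model 1's low-D /
fast-decay parameterization already represents an effectively immobilized
pool, and keeping one pool makes the equal-mass constraint exact.

## B-cell agents

Each agent carries CXCR5 in three pools (free, ligand-bound, internalized)
with mass-action kinetics: binding k_on·c, unbinding k_off, internalization
of bound receptor k_i, recycling k_re. Defaults (k_on = 1 per concentration
per s, k_off = 0.1 s⁻¹, k_i = 0.1 s⁻¹, k_re = 0.005 s⁻¹) encode chronic
desensitization under sustained ligand — receptor internalization on
persistent exposure with slow (minutes) resensitization — which is what
silences guidance in a homogeneous chemokine bath. Pools are integrated by
explicit Euler substeps sized so per-substep fractional changes stay below
0.4; where the kinetics are far faster than the motility step even at the
substep cap (200), pools are set to the algebraic equilibrium they would
reach within the step. Receptor number is conserved to rounding either way.

Motion is a persistent biased random walk at the motility time step
(default 10 s; 5 s in desk-scale experiments). The new heading is the
normalized sum of three terms: `persistence` × previous heading, a unit
random vector, and a chemotactic term chi · w · ∇c/|∇c|. The weight w is the
difference in equilibrium surface-receptor occupancy across the cell body,

  w = [φ(c + |∇c|·d/2) − φ(c − |∇c|·d/2)] · (R_free + R_bound)/R_total,

with φ(c) = c/(K + c), K = (k_off + k_i)/k_on and d the cell diameter
(8 µm). This is the standard receptor-limited sensing argument: a cell
compares front and back occupancy, so the signal vanishes both where the
gradient is shallow relative to the concentration and where the
concentration saturates the receptors — and is further scaled down when
receptors are internalized. A design alternative (weighting the normalized
gradient by R_b/R_total alone) was rejected because it reads arbitrarily
shallow gradients at full strength: any smooth field then acts as a
long-range beacon, which inverts the immobilized-vs-soluble scanning
comparison and contradicts receptor physics. Speed is drawn per step around
v_mean (default 6 µm min⁻¹, a typical naive B-cell speed; 20% CV);
boundaries reflect. Contacts are logged when a cell centre comes within
`contact_radius` (10 µm) of a stromal node; the scanning rate counts unique
nodes per cell per hour. Cell–cell exclusion and ligand consumption are off
by default (consumption is available as a flag).

The 13 emulated parameters are fixed as: D, λ, secretion_fdc, secretion_rc,
k_on_ecm (field); k_on, k_off, k_i, k_re, R_total (receptor); v_mean,
persistence, chi (motility). This mapping is a documented contract so the
surrogate dimensionality is stable.

## Migration statistics

Tracks are resampled to a 30 s cadence (a typical two-photon sampling
interval) before analysis. Speed is the mean step displacement over the
sampling interval; the meandering index is net displacement over path
length; the motility coefficient is the slope of an origin-constrained OLS
fit of the time-averaged MSD over lags up to 25% of track length, divided by
2·dim; the scanning rate divides unique stromal contacts by cell-hours.
Per-run values are medians over cells. The experimental calibration targets
for speed/meandering/motility default to 6 µm min⁻¹ / 0.35 / 15 µm² min⁻¹ —
plausible naive-B-cell values supplied as configuration, to be replaced by a
user's own measurements for faithful calibration.

## Emulation

Designs are Latin hypercube samples (one point per equal-width stratum per
dimension, random pairing). Each design point is simulated with replicate
seeds and summarized by the replicate median of each emergent statistic. One
surrogate per statistic maps the 13 normalized parameters through three
sigmoidal (logistic) hidden layers to a single linear output; inputs and
outputs are min–max normalized, weights are fit by Adam on squared error,
and hidden sizes are selected by k-fold cross-validated RMSE (default grid
(24,16,8)/(16,8,4) at k = 3 for desk scale; the full 27-point {8,16,24}³
grid at k = 5 in the paper-scale profile). The design is split 75/15/10 into
train/test/validation and all three RMSEs are reported. Trained surrogates
serialize to JSON (weights + normalization bounds) and evaluate at far more
than 10³ predictions per second, which is what makes population-scale
optimization affordable.

## Multiobjective optimization

NSGA-II is implemented directly: fast nondominated sorting (vectorized
dominance matrix), crowding-distance selection, binary tournaments,
simulated binary crossover (η = 15) and polynomial mutation (η = 20, rate
1/13) — the standard operator defaults for box-bounded real-valued NSGA-II. Maximized
objectives are sign-flipped internally and reported in natural sense. The
four objectives are |emulated − target| for speed, meandering index and
motility coefficient, and the scanning rate (maximized). Conflict analysis
reports Spearman correlations between the minimization-form scanning
objective and each fit objective over the front; negative values mean the
objectives trade off. Population 100 / generations 250 by default
(80/80 in the desk-scale profile); the hypervolume against a reference point
is tracked per generation for bi-objective problems and verified against
the analytic front of a closed-form test problem.

## Spatial autocorrelation

Images are binned into square bins of area 14.44 µm² by default (mean
intensity per bin; partial edge bins dropped; at least 2 bins per axis).
Moran's I is computed per distance class with binary weights over bin-centre
distances, classes one bin side wide out to half the grid diagonal.
Significance is a two-sided permutation test (value relabeling, default 999
permutations, the observed value included in the null count).
D_uncorrelated is the centre of the first class whose p-value exceeds 0.05,
with no multiplicity correction — the earliest distance at which the
autocorrelation stops being significant; the class width, α and correction
choice are recorded in the result metadata. When applied to simulated chemokine fields, the analysis
should be run on a window inside the follicle (as the microscopy frames
are): a whole-domain slice is dominated by the follicle-versus-outside
intensity trend, which keeps every distance class significant on a
noise-free field.

## Single-molecule track analysis

Tracks shorter than five consecutive frames are rejected at ingest. The
per-track diffusion coefficient is the slope/4 (2D) of an unweighted linear
fit to the time-averaged MSD at the first four frame lags — the short-lag
estimator; the literal reading "fit to the first four positions" is not a
diffusion estimator, and this interpretation is flagged here deliberately.
Negative fitted slopes floor at D = 0 with a flag; upward-curving MSDs are
flagged super-diffusive. Localization noise adds a constant 4σ² offset to
every MSD point (σ = 40 nm default); because the fit carries an intercept
the offset does not bias the slope, and an explicit noise-floor subtraction
is available (off by default, so that raw uncorrected estimates are reported unless asked for). The
synthetic track generator draws 2D Brownian increments of variance 2DΔt per
axis at 513 Hz plus independent Gaussian localization noise, giving ensemble
MSD 4DkΔt + 4σ² exactly. Mobility reports give per-condition medians, IQRs,
the immobile fraction below a threshold (default 0.1 µm² s⁻¹, adjustable;
the cut is a convention, so it is exposed rather than fixed) and a
two-sided Mann–Whitney U comparison.

## Scaling and what the tests do and do not show

The shipped experiment profiles are desk-scale: the model comparison uses a
60-node follicle (radius 75 µm), 10 cells, 20-minute runs and 50 replicates
per model; the emulate-then-optimize campaign uses the full-size follicle
geometry (its gradient length scales are the object of study — shrinking
the domain compresses the screening-length axis and distorts the
diffusion-parameter preference) with a 100-point design, 3 replicates and
80/80 NSGA-II settings. `paper_scale_config` restores the full study sizes
(200 replicates; 3000 × 100 design; 100/250 optimization; 27-architecture
grid) and is compute-heavy.

The synthetic data emulate the structural statistics of measured follicles,
screened-diffusion chemokine physics and receptor-limited sensing; they do
not emulate imaging noise, cell–cell crowding, stromal remodelling,
chemokine processing by proteases, or co-expressed chemokine axes. Passing
tests therefore demonstrate internal consistency of the models and
reproduction of the reported statistical anchors under these assumptions,
not biological validity of any single parameter value.

## Numerical choices

Explicit FTCS with a positivity-preserving dt guard; CG steady-state solves
at rtol 1e−12; receptor Euler substeps capped at 200 with equilibrium
fallback; MSD fits through the origin for cell motility, with intercept for
single-molecule tracks (the noise floor lives in the intercept); ring
lattice degree rounded down to even for ω; seeded `numpy.random.Generator`
everywhere, with child seeds drawn below 2³¹; ties in the Vargha–Delaney A
count one half.
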