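# Methods

## Scope and model structure

`strpfr` predicts the transcriptional and translational response of a
chemostat *E. coli* population that is repeatedly exposed to nitrogen
starvation in an STR–PFR scale-down loop. It deliberately separates
three layers, each solvable on its own:

1. a **deterministic single-cell lattice model** of one induction
   episode (transcription, translation, 5'→3' degradation of one
   polycistronic operon);
2. a **stochastic cell-distribution model** of the reactor system
   (which cell is where, when);
3. a **superposition layer** that combines the two through per-cell
   PFR-entry flags.

The separation rests on a strong assumption: cells travel through a
*frozen* bioreactor background. A PFR passage always triggers the same
episode, cells do not alter their environment, and episodes on the
same cell simply add. This keeps the population problem linear in the
(cheap, precomputed) episode and makes 10,000-cell simulations of many
hours run in seconds.

## Single-cell lattice model

DNA and mRNA are discretized per nucleotide; positions are 1-based on
the transcript, with 0 the reserved pre-initiation state.

**Polymerases.** Initiation — modelled as the first elongation step —
occurs only inside the induction window `t_ind` (default [30, 125] s
after PFR entry: a 30 s derepression delay, closed at PFR exit) and
only when the trailing polymerase has cleared `delta_x` nucleotides.
Elongation proceeds at `velo_rnap` unless the leader is within
`delta_x`. Once committed, a polymerase always runs to the terminator
(attenuation is reduced to exactly this simplification: read-through
during starvation, no initiation otherwise). The transcript length
equals the polymerase position while attached.

**Ribosomes.** Each gene region carries a translations-per-mRNA quota
`n_tl_max` (defaults 4/4/5/10/10 for trpE/D/C/B/A; the trpL leader
peptide carries 0 and is excluded from protein accounting). A ribosome
loads at the gene's first coding nucleotide when at least `delta_y`
nucleotides beyond it are synthesized, the nearest ribosome ahead has
cleared `delta_y`, and the quota is not exhausted; it elongates at
`velo_ribosome` subject to the same spacing and to a `delta_y` gap
behind the synthesis front, and detaches past the stop codon,
incrementing the protein count. Quotas can be derived for other genes
with `translations_per_mrna`, the protein/mRNA turnover ratio
`N = (c_P k_deg^P)/(c_m k_deg^m)` with growth dilution as the protein
loss term (`k_deg^P = μ`) and `k_from_halflife` for mRNA decay
(2 min ↦ 20.79 h⁻¹).

**RNases.** One degradation front per transcript starts at the 5' end.
It may not advance into gene *g* until the gene's quota is spent, and
it keeps a `delta_z` steric gap to the hindmost obstacle ahead of it —
the hindmost ribosome still on the strand, or the synthesis front
while the polymerase is attached. (The front case covers regions with
quota 0, where no ribosome ever intervenes; without it the RNase would
ride one nucleotide behind the polymerase and the leader transcript
would never be observable.) A strand is gone when the front reaches
its end; the episode length Δt is the time from PFR entry until the
last strand is gone — 493.2 s with defaults, just under one mean
reactor cycle (~497 s).

**Two transcript readouts.** The per-gene mRNA level is reported in
two conventions, recorded side by side in the trace:

* `mrna` (*intact*): a strand counts toward gene *g* while the gene is
  fully transcribed and the degradation front has not reached its
  first coding nucleotide. Contributions are clamped at zero — a
  region degraded before the gene completed never counts. Under the
  default geometry only genes shorter than
  `n_tl_max·delta_y + delta_z` can ever be intact-counted, which is
  why trpA (807 nt < 1100 nt) is the only late residual.
* `mrna_partial` (*presence*): a strand counts while any part of the
  gene region exists (synthesis has entered it, degradation has not
  left it). This is what a hybridization measurement sees, and it is
  the readout in which every structural gene peaks at the full strand
  count (20).

Population superposition and the census use the intact readout; PFR
port profiles and exports carry both columns.

**Discretization and update order.** Time advances in fixed steps,
default `dt = 1/max(velocity)` so that each agent hop is exactly one
nucleotide (general velocities are handled by fractional-step
accumulators that emit whole-nucleotide passes). Within a step the
order is RNases, ribosomes, polymerases, then promoter initiation;
within a species the most-downstream agent moves first. The initiation
gap condition is evaluated on the trailing polymerase's begin-of-step
position, which makes the initiation train exactly periodic with
period `delta_x/v` and reproduces the continuous-time count
`1 + floor((t_end − t_start)·v/delta_x)` for every window, velocity
and spacing; evaluating after the same step's elongation would
overcount by one for window·velocity ≡ −1 (mod `delta_x`). Spacings
never drop below `delta − v·dt` through movement (a quota ribosome may
legitimately *load* right next to a gated RNase, which is why the
invariant checker bounds RNase–ribosome order, not distance). The
module is free of randomness; traces are bit-identical across runs.

## Cell-distribution model

The STR census `n_str` drives three first-order channels:
PFR entry (`n_str·q_pfr/v_str`), washout (`n_str·q_feed/v_str`), and
division at the **constant** rate `n0·D`. Tying division to the
initial census rather than the current one is intentional: the pair
washout/division then has the self-stabilizing balance point
`n_str* = n0·D·v_str/q_feed` (≈7467 cells with defaults); a per-capita
division rate would make the population drift. Daughters are default
cells — no flags, no inherited expression program; mothers are
untouched. All three channels act on STR residents only.

Waiting times are exponential with the summed rate and the channel is
chosen by the cumulative-rate rule. PFR transit is a deterministic
delay `tau_pfr` (125 s, the *measured* residence time; the value
recomputed from volume and flow, 126.7 s, is exposed separately but
the sampling ports and the induction window are tied to the measured
number). Scheduled returns are interleaved exactly: whenever a return
falls inside a drawn waiting time, the return executes and the
exponential clock simply restarts — memorylessness makes this exact,
not an approximation. Returns form a FIFO queue because the delay is
constant. A single `random.Random(seed)` stream drives everything;
identical seeds give identical event logs. The last drawn event may
overshoot the requested duration and is dropped from the log (it is
unobservable inside the simulated window).

With defaults the tracked-cell split settles at ≈74.9% STR / 25.1%
PFR, matching the liquid-volume split (74.7/25.3) — compartment
residence is purely flow-determined.

## Coupling and the induction census

A cell's transcript level at time *t* sums the episode table at
`t − t_flag` over flags younger than Δt; protein sums the table while
an episode runs and the episode's terminal value afterwards. Episode
lookups use nearest-grid-point indexing on the `dt` grid (counts are
integers; interpolation would invent fractions). Washout deletes a
cell's entire contribution; newborn daughters contribute zero until
their first own passage. The vectorized population trajectory is
exactly the brute-force sum of per-cell lookups (asserted against it
in the tests).

A cell is **induced** at *t* if at least one flag satisfies
`t − t_flag ≤ Δt`, i.e. mRNA from that passage may still exist;
**multiply induced** means two or more such flags (the cell re-entered
the loop while a previous episode was still running). With defaults
the long-run census is ≈28.5% not induced / 47.4% once / 24.2%
multiple. These fractions are sharply sensitive to Δt: the inter-flag
interval is `tau_pfr` plus an exponential STR wait (mean
`v_str/q_pfr` ≈ 373 s), so each minute taken off the active window
moves several percentage points from the "multiple" to the "not
induced" class. Δt itself depends only weakly on the gene boundaries
(through when trpA's last ribosome loads), so replacing the bundled
annotation shifts the census by well under a point.

Protein equilibrates far more slowly than mRNA. Transcript levels are
stationary one episode after connecting the loop (~8 min): only flags
younger than Δt contribute. Per-capita protein instead relaxes at the
effective drain rate `n0·D/N ≈ 0.2 h⁻¹` (daughter influx plus washout
— exactly how the model realizes degradation-free protein loss,
`k_deg = μ`), i.e. a 5 h time constant: it is at ~84% of its plateau
at 10 h and crosses 95% around 15–18 h. The analytic fixed point
`c = r_translation/k_eff` agrees with the simulated plateau to a few
percent, closing the loop between the episode's translation rates
(9.7/12.2/24.3 copies min⁻¹ for TrpE(D)/TrpC/TrpB(A)) and the
long-run population state.

## Default parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `velo_rnap/ribosome/rnase` | 21 | nt s⁻¹ | common elongation rate of all three species |
| `delta_x/y/z` | 100 | nt | minimum spacings (RNAP–RNAP, ribosome–ribosome, RNase–obstacle) |
| `t_ind` | [30, 125] | s | induction window per PFR passage |
| `dt_step` | 1/21 | s | lattice step (one nucleotide per hop) |
| operon length | 6726 | nt | trpL-EDCBA transcript |
| `n_tl_max` | 4/4/5/10/10 | – | translations per mRNA, trpE…trpA |
| `v_str`, `v_pfr` | 1120, 380 | mL | compartment volumes |
| `q_pfr`, `q_feed` | 180, 5 | mL min⁻¹ | loop and harvest flows |
| `dilution_rate` | 0.2 | h⁻¹ | chemostat dilution rate |
| `n0` | 10,000 | cells | tracked census at connection |
| `tau_pfr` | 125 | s | deterministic PFR transit |

Gene boundaries in the bundled annotation follow the *E. coli* K-12
CDS lengths (trpE 1563, trpD 1596, trpC 1359, trpB 1194, trpA 807 nt),
shifted so trpA ends on the last transcript nucleotide; boundaries
shift protein appearance times by seconds and leave all integer yields
unchanged. They live in a plain TSV so users can substitute exact
coordinates.

## What the simulated data does and does not emulate

The population run *is* the data-generating process here: no external
datasets are consumed. It emulates the stationary chemostat with an
abruptly connected starvation loop — uniform initial STR population,
flow-proportional compartment exchange, flat PFR residence times, and
identical, deterministic induction episodes. It does **not** emulate
cell-to-cell kinetic variability (no stochastic initiation or
elongation noise), residence-time distribution inside the PFR,
metabolic feedback of cells on substrate fields, attenuation
thermodynamics, or microarray measurement noise. Tests passing on this
generator therefore validate the mechanics and their couplings, not
the biological parameter values; against real reactors the sharpest
predictions are the ratios and time scales (compartment split, census
classes, minutes-vs-hours separation), not absolute copy numbers.

## Numerical choices and degenerate inputs

* Float guards: window membership and accumulator emission use a 1e-9
  tolerance so that tick times like 630·(1/21) compare equal to 30 s.
* Zero-width windows (`t_ind = [a, a]`) admit exactly one initiation.
* Quota-0 genes gate nothing and never count protein.
* `q_pfr = 0` yields an empty flag log and a fully naive census;
  an empty system with all rates zero raises instead of spinning.
* Ports outside `[0, tau_pfr]` and census times outside the simulated
  span raise `ValueError`.
* Episodes that outlive the `horizon` argument return a trace flagged
  `truncated` plus a warning rather than failing.

## Problem sizes

The bundled analyses use the full 10,000-cell census for 2 h of
simulated time (stationary split and induction census; ~300k events,
seconds of wall time). The slow protein equilibration is resolved on a
scaled-down census of 1,000 cells over 24 h: per-capita quantities are
independent of the census size, which only sets their shot noise.

## Known limitations

* The intact-transcript readout makes long genes with small quotas
  invisible at the mRNA level (degradation front passes their start
  before synthesis passes their end); use the presence readout when
  comparing with hybridization data.
* The induction census inherits the sharpness of the episode-length
  cutoff; a graded "induced" definition (e.g. mRNA above a threshold)
  would soften the class boundaries.
* Division resets daughters completely; partitioning of existing
  protein between mother and daughter is not modelled, so per-capita
  protein decays only through population turnover.
* The PFR is unresolved internally: port profiles are episode lookups,
  valid exactly because transit is plug flow.
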