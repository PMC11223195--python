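# Methods

## Scope and data model

The package analyses a receptor/adaptor TM helix trimer: one TREM2-like
receptor chain (default chain C) and the two chains of a DAP12-like
adaptor homodimer (chains A and B). All analyses operate on an MDAnalysis
`Universe` (PDB topology plus multi-model PDB or any MDAnalysis-readable
trajectory); residue numbering is taken verbatim from the input files, and
chain roles are assigned in configuration, not inferred.

## Kink angle

The kink metric is the 4-point Cα construction: the angle between
v₁ = Cα(vec1_end) − Cα(vec1_start) and v₂ = Cα(vec2_end) − Cα(vec2_start),
defaulting to residues 20→24 and 32→36 on the receptor chain, clipped into
[0, 180]°. Summary statistics are the arithmetic mean, the SEM over frames
(σ/√n — the error-bar convention most consistent with ±0.1° over a few
hundred frames; block averaging is not applied), and the mode of a
histogram with bins [k·w, (k+1)·w) anchored at 0° (w = 1° by default),
reported as the bin centre with ties broken toward the lower bin.

The metric has a systematic offset: on an ideal α-helix (1.5 Å rise,
2.3 Å Cα radius, 100°/residue) a 4-residue Cα vector is tilted 14.69° off
the helix axis, so a perfectly straight helix measures 25.378° and a
programmed segment-axis bend of a° measures a° plus an azimuth-dependent
offset (102.33° for a 100° bend in the default kink plane). The offset is
a property of the published metric, not an artefact; tests freeze the
straight-helix value and verify mode recovery against the noiseless
4-point value of each programmed bend.

## Contact maps

A residue pair is in contact in a frame iff the minimum distance between
its atom sets is ≤ cutoff (inclusive; the boundary convention is
unobservable on fixtures which avoid exactly-at-cutoff distances). Levels:
`c_alpha` (Cα only, default 11 Å) and `all_atom` (all atoms including
hydrogens, default 3 Å; a heavy-atom-only switch is provided).
Persistence is the fraction of frames in an inclusive frame window;
windows given as times ("175ns:225ns") map to the nearest frame at or
after the start and the last frame at or before the stop.

Persistence filtering retains pairs with persistence strictly > 0.5
(" more than half of the window"). Consensus merging counts, per residue
pair, the number of persistent maps containing it — conventionally the six
(system × adaptor chain) all-atom maps of a three-system comparison — and
retains pairs with count ≥ 3. The merged count matrix (0–6) is itself the
"merged total contacts" view, since the ≥ 3 rule requires a count rather
than a union. Retained pairs are classified non-exclusively:
`hydrophobic` iff both residues are in {A, V, L, I, M, F, W, P} (Trp
included because it acts as a hydrophobic partner at this interface; Gly
excluded), `salt_bridge` iff the residue identities are oppositely charged
(K/R vs D/E), `hydrogen_bond` iff the supplied occupancy table has a
non-zero row for the pair; pairs matching no rule are flagged.

## Hydrogen bonds and salt bridges

A donor–hydrogen···acceptor triple is formed in a frame iff the
donor–acceptor distance is ≤ 3.0 Å and the donor–H–acceptor angle is
≥ 150°. The distance definition defaults to heavy-atom donor–acceptor
(the convention of the standard analysis tooling); a hydrogen–acceptor
mode is provided because published criteria are often ambiguous, and the
synthetic fixtures satisfy/violate both definitions identically so the
choice cannot silently change results. For multi-hydrogen donors (lysine
NZ with HZ1–HZ3) a frame counts if any hydrogen passes the angle test —
occupancy tables are keyed by (donor atom, acceptor atom), not by
hydrogen.

The default registry monitors, against both adaptor chains: K26 NZ→D16
OD1, K26 NZ→D16 OD2, K26 NZ→T20 OG1, W34 NE1→T20 OG1 and W34 NE1→T20
backbone O. Aggregate pair occupancy is the plain sum of the per-label
rows (the published arithmetic, e.g. 24.85 + 60.35 → 85.2%), rounded
half-up to 1 decimal for reporting (tables round half-up to 2 decimals);
the raw sum is kept and flagged when it exceeds 100%, since summing
double-counts frames where both component bonds are formed. Salt-bridge
occupancy uses the minimum distance between charged heavy-atom groups
with a 4.0 Å cutoff — the common literature convention; no energetic
scoring is attempted.

## The synthetic generator

`helixgen` replaces production MD with geometry whose every analysed
property is programmed:

* **Ideal helices** — Cα(i) = (r cos kτ, r sin kτ, k·d), k = i−1, with
  textbook α-helix defaults (d = 1.5 Å, r = 2.3 Å, τ = 100°/residue);
  N, C and O ride on scaled cylinders at fixed phase/height offsets.
  Sequences default to poly-alanine with the interface residues
  substituted at their published numbering (receptor: L19, L24, K26, W34;
  adaptor: I12, D16, T20, I23), since the full construct sequence is not
  available; this is a declared approximation.
* **Kinks** — all residues beyond the hinge rotate rigidly about an axis
  through the hinge Cα perpendicular to the pre-hinge segment axis, at a
  configurable azimuth. The rotation angle is exact segment-axis ground
  truth; a least-squares cylinder fit (zero-residual at the optimum for
  ideal helices) serves as the independent axis oracle and recovers
  programmed bends to < 0.01°.
* **Side-chain probes** — NZ/HZ1–3, OD1/OD2, OG1, NE1/HE1 are placed at
  short idealized offsets from their parent Cα, pointing radially outward.
  Offsets are deliberately compact (≤ 3 Å + 1 Å hydrogens) so that with
  the default bundle placement — adaptor chains at ±13.5 Å with a +15 Å
  z-stagger aligning D16 with K26 — no unscheduled cross-chain atom pair
  ever comes within the 3 Å all-atom cutoff, while Cα–Cα separations
  (≈ 9 Å at closest) keep the 11 Å Cα maps well populated.
* **Schedules** — each monitored H-bond carries a boolean frame mask:
  quota mode realises exactly round(p·n) satisfying frames at seeded
  random positions (for exact tests), Bernoulli mode draws frames
  independently (for statistical tests). On "on" frames the acceptor atom
  is placed 2.8 Å from the donor along a donor-hydrogen direction
  (tilted ≤ 15°, giving D–H–A ≥ 160°); on "off" frames the same direction
  at 5.0 Å — both distance definitions are satisfied/violated together
  with wide margins. Two schedules moving the same acceptor atom are
  rejected. Chain-B acceptors are placed along the receptor donor's
  hydrogen directions even though those point toward chain A; the
  resulting geometry is not a physical side-chain conformation, but the
  occupancy/contact ground truth it encodes is exact.
* **Noise** — isotropic Gaussian per atom per frame, default σ = 0.1 Å,
  excluded from schedule-involved atoms so schedules stay exactly true.
  The default is chosen so that 1°-resolution kink-mode recovery is
  well-posed (angle jitter std ≈ 1.8° at this σ); it models residual
  per-atom jitter about an aligned mean structure, not the correlated
  collective motions of real MD.
* **The three reference systems** — `6z0g_like` (receptor kinked 100° at
  residue 26, bending away from both adaptors; chain B moved to 18 Å,
  out of Cα contact range: the single-chain-engagement state),
  `6z0i_like` and `af_like` (straight receptor engaging both chains),
  with quota schedules mirroring the published per-bond occupancy
  pattern: K26/D16 on chain A only in the kinked system, on both chains
  in the unkinked systems, plus the transient K26/T20 and the AF-specific
  W34/T20 bonds. Default 301 frames at 1 ns/frame nominal spacing.

What passing tests on these fixtures shows: the estimators compute
exactly the defined statistics and recover known ground truth under
Gaussian noise. What they do not show: robustness to correlated dynamics,
conformational substates, periodic-boundary imaging artefacts or missing
atoms in real MD data — real trajectories should be imaged/made whole
before analysis, as the package computes plain Euclidean distances.

## Numerical and design choices

* Trajectories are written as multi-model PDB (byte-deterministic given a
  seed; coordinates at the format's 0.001 Å resolution), optionally DCD;
  ground truth (seed, masks, kink) goes to a JSON sidecar.
* The pipeline treats each configured trajectory independently; replica
  pooling is left to configuring replicas as separate systems. The
  per-system window restricts contact maps only (the published windowed
  analysis); kink and occupancy statistics use all frames.
* With fewer than three systems the consensus step is skipped with a
  logged notice rather than merging an incomplete map set.
* Analysis outputs embed a config hash; reruns with identical config and
  seed are byte-identical, which the test suite asserts.
* Problem sizes in tests and the acceptance script (301-frame reference
  runs, 2000-frame recovery studies, 20-seed replication, ≤ 50-frame
  oracle fixtures) are chosen as the smallest sizes at which the
  statistical contracts are sharp.

## Known limitations

* The 4-point kink metric is the only kink estimator exposed (by design,
  matching the published analysis); the cylinder-fit axis oracle is
  internal ground-truth tooling.
* Occupancy aggregation by summation can exceed 100% when component bonds
  co-occur; the flag and raw union are reported but the published
  convention is kept for comparability.
* The generator produces protein atoms only — no lipids, water or ions —
  and its helices are rigid apart from programmed kinks and white noise.
* PDB chain ids limit the generator to single-character chain names.
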