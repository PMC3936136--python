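# Methods

## Model and procedure

The package ranks database protein chains by structural similarity to a
query using two nested local alignments and a rigid superposition.

A chain is read from PDB text as its Cα trace (one coordinate per
residue).  Secondary structure comes from the file's HELIX/SHEET
records: residues covered by a HELIX record of any class are H,
residues covered by a SHEET record are E, everything else is L, with
HELIX winning on overlap.  No geometric assignment (DSSP/STRIDE) is
attempted — the three-letter alphabet collapses helix subtypes anyway,
and loops are treated leniently by the scoring rules, so record-based
labels keep the tool free of an external assignment step.  Results on
real PDB entries will depend on whoever produced those records.

**Phase 1.** The per-residue SSE string is run-length encoded into SE
regions [type, length].  Region pairs score
δ = σ·(1 − |L_d − L_q|/(L_d + L_q)) with σ ∈ {1, 0.5, 0} by the
type rules (matching H/E = 1, any loop = 0.5, H-vs-E = 0).  δ lives in
[0, σ]: identical regions score exactly σ, and for fixed σ the reward
decays with the relative length difference.  The length damping is
applied uniformly, including the σ = 0.5 loop cases.  A query profile
(region × {H, E, L, neutral} table of σ, stored in the byte encoding
0→0, 1→1, 0.5→2) replaces pair lookups during scans; arithmetic always
uses the decoded reals.

**Qualification.** Score(Q,D)/Score(Q,Q) ≥ Q_t decides promotion to
phase 2.  The denominator is the phase-1 self-score, which has the
closed form #(H/E regions) + 0.5·#(L regions) (every diagonal reward is
positive, so no gap can beat the full diagonal).  Q_t = 0 bypasses the
filter entirely; Q_t defaults to 0.2, which in practice prunes clearly
dissimilar topologies while keeping short local similarities alive.

**Phase 2.** Residue descriptors <|C_i|, γ_i, SSE_i, r_i> are aligned
with the reward ss = w_C·exp(−Δ|C|²) + w_γ·exp(−Δγ²) + w_SSE·σ +
w_r·B(r_q, r_d), weights defaulting to 1.  B is BLOSUM62 min–max
normalized to [0, 1] globally over the 20 standard residues (raw range
−4…11); per-row or logistic normalizations were rejected as
irreproducible.  Unknown residues ('X') get B = 0.  The reward is pure
(≥ 0): divergence costs through the Gaussian fall-off, the local zero
clamp and the gaps, with no explicit mismatch penalty.

**Phase 3.** For the top M hits the full similarity matrix is rebuilt,
the path is backtracked from the argmax, and the aligned Cα pairs are
superposed by the SVD Kabsch algorithm with determinant correction
(reflections forbidden); RMSD is reported over the N aligned pairs.
Sets with fewer than 3 pairs or rank-deficient (collinear) geometry are
rejected as errors rather than silently fitted.

## Alignment core

Both phases share one affine-gap local DP with zero boundary and
clamped cells.  The gap recurrences open from the adjacent similarity
cell at cost g_O and extend at g_E, i.e. a run of k gaps costs
g_O + (k−1)·g_E.  The database scan keeps one row of H, one row of F
and a scalar E (O(m) memory); the full matrices are materialized only
for backtracking.  Fixed conventions, chosen for reproducibility where
any choice is defensible:

- argmax ties break toward the smallest query index, then the smallest
  database index (row-major first occurrence);
- backtracking prefers diagonal, then vertical gap, then horizontal
  gap, with numeric consistency checked to 1e-9;
- gap penalties default to g_O = 1.0, g_E = 0.1 (phase 1) and
  g_O = 2.0, g_E = 0.2 (phase 2).  No published values exist for these
  constants; the defaults make a single weak region match (reward ≤ 1)
  unable to beat opening two gaps, and every entry point accepts other
  values.

γ is stored in radians (switchable to degrees at descriptor build).
Radians keep angle differences within ~π so the Gaussian exp(−Δγ²)
retains dynamic range; with degrees the term would collapse to 0 for
all but near-identical angles.  Terminal residues with undefined
vector/angle carry zeros, matching the zero padding of cached chains;
zero-reward padding cells provably never change a local score.

## Database cache

`build-db` parses every chain of every `*.pdb` file, stores per-chain
records (id, reduced chain, descriptor chain, Cα coordinates — the
coordinates are kept so top hits can be superposed without re-reading
source files) in a little-endian binary file with magic bytes, a format
version and length-prefixed records, sorted ascending by chain length.
A version mismatch demands a rebuild.  The blocked view
(`iter_blocks`, 32 chains per block, zero-padded feature arrays) is
computed on demand rather than stored, so decode(encode) is exact;
tests pin that scores are independent of both padding and iteration
order.

## Synthetic data

The fixture generator emulates the geometry the descriptors measure:
helices as 1.5 Å-rise, 2.3 Å-radius, 100°/residue spirals; strands as
3.4 Å-rise near-linear segments with small alternating wobble; loops as
3.8 Å-step random walks; segments chained in seeded random
orientations.  Consecutive Cα distances land near the physical 3.8 Å,
so c_len and γ distributions are realistic, but the decoys have no side
chains, no excluded volume, random sequences and no evolutionary
structure.  Passing tests therefore demonstrate the correctness of the
representation, scoring, filtering and superposition machinery — not
retrieval quality on real folds, which additionally depends on the SSE
assignment source and on how real structural redundancy interacts with
Q_t.

The demonstration database is 200 chains of 30–90 residues with mixed
H/E/L layouts (runs of 2–12 residues), a small-protein-domain scale
that exercises multi-block caching and all threshold regimes; unit
tests use a 20-chain version of the same recipe.  All generators take
explicit seeds and are bitwise reproducible.

## Known limitations

- Secondary structure is only as good as the HELIX/SHEET records; files
  without them reduce phase 1 to loop-vs-loop scoring (σ = 0.5
  everywhere).
- Only the first model of multi-model (NMR) files is read; altloc
  handling keeps the first conformer.
- Phase 1 alignment paths are not projected into phase 2; the phases
  share only the qualification ratio.
- Superposition is single-pass least squares — no outlier rejection, no
  TM-score, no flexible alignment.
- Scores are not length-normalized across queries; ratios (phase 1) and
  ranks (phase 2) are comparable, raw scores between different queries
  are not.
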