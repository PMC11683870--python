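# Methods

This note documents the models, scores and numerical choices behind
`molminer`, and what its synthetic test conditions do and do not show.

## Molecular string representation

Generation operates on a valence-safe token dialect rather than SMILES.
SMILES syntax (bracket matching, ring-bond digit pairing) makes most
random strings unparseable, so a SMILES language model wastes capacity on
syntax.  The dialect instead follows SELFIES-style derivation rules:
bond-prefixed atom tokens (`[C]`, `[=C]`, `[#C]`, ...) extend a chain,
`[Branch1]`/`[Branch2]` open side chains whose length is read from the
following token(s) re-interpreted as base-16 digits, `[Ring1]`/`[Ring2]`
(and `[=Ring*]`) close rings against atoms a decoded distance back, and
`[Break]` terminates the molecule.  Requested bond orders are capped by
the remaining valence of both partners, and impossible branch/ring
instructions are skipped, so *every* in-vocabulary token sequence decodes
to a valid molecule or to the explicit empty marker.  "Invalid" samples
are therefore exactly the empty decodes (e.g. an immediate break token).

Element valences are capped at the lowest standard valence (C 4, N 3,
O 2, S 2, P 3, halogens 1).  This guarantees that any partial derivation
is completable with implicit hydrogens and hence always sanitizes, at the
cost of excluding hypervalent groups (sulfones, phosphates) and charged
or multi-fragment species from the encodable chemistry.  Sequences that
hit the length cap (default 100 tokens) without a break are decoded from
the prefix and flagged.  Canonical identity is the isomeric canonical
SMILES, so stereoisomers count as distinct molecules.

The encoder is a depth-first traversal of the kekulized molecular graph
emitting the same token language (ring closures at the later endpoint,
all-but-last children as branches), which makes encode/decode an exact
round trip on every supported molecule; this is asserted corpus-wide in
the tests.

## Generator

The policy is an autoregressive language model over the token alphabet:
embeddings (default 400-d) feed a stack of LSTM cells (default
1152/1152/400 units) with a linear softmax decoder sized to the
vocabulary.  DropConnect masks the recurrent weight matrices once per
forward/backward pass; embedding, inter-layer and output dropout use the
usual inverted scaling.  The four dropout rates (0.002 / 0.02 / 0.015 /
0.01) can be scaled jointly by a single multiplier.  The implementation
is plain numpy with hand-derived backpropagation through time; gradient
correctness is pinned by finite-difference checks in the suite
(directional derivatives, relative error < 1e-4).

Supervised pretraining minimizes teacher-forced categorical
cross-entropy with the break token appended to every sequence, using
Adam under a one-cycle learning-rate schedule (default peak 5e-4, batch
512, weight decay 0.01, 30 epochs — the full-scale recipe).  A 5%
held-out split tracks validation loss.  Desk-scale runs (the test-suite
and the acceptance measurements) shrink the model to 64-d embeddings
with 128/128 units, train 20 epochs at peak 3e-3 on a 5,000-molecule
synthetic corpus, and set weight decay to 0: at this parameter count the
full-scale decay constant visibly biases the softmax toward uniform,
which leaks probability onto the break token at the first position —
regularization strength has to follow model scale.  Fine-tuning
continues cross-entropy training on a scaffold-bearing corpus at a lower
peak rate and returns a copy of the policy.

Sampling is ancestral at temperature 1, recording per-token
log-probabilities for reinforcement learning; a fixed generator seed
reproduces sequences bit for bit when dropout is off.

## Rewards

The terminal reward of a decoded molecule X is a weighted sum of clipped
terms, R(X) = sum_i lambda_i clip_i(S_i), kept non-negative by
construction: docking scores (kcal/mol, negative favourable) contribute
max(-S_vina, 0); the drug-likeliness score contributes max(S_DL, 0);
similarity and interaction terms are non-negative already.  Duplicate
molecules inside one batch share the mean of their docking-derived terms,
since docking engines are stochastic under reseeding.

**Drug-likeliness.**  Thirteen 2D descriptors (sp3-carbon fraction,
heavy-atom count, heteroatom fraction, H-bond donors/acceptors, rotatable
bonds, aliphatic and aromatic rings, molecular weight, Crippen alogP,
topological polar surface area, structural-alert count, largest ring
size) are histogrammed over a reference corpus — 64 fixed-width bins
spanning the 1st-99th percentile for continuous descriptors, unit bins
for counts.  Each descriptor gets a Shannon entropy S_i (floored at 1e-3
nat) and weight sigma_i proportional to 1/S_i (normalized to sum to 1),
so narrow reference distributions dominate.  The score is the weighted
mean of log bin-probabilities with a 1e-6 probability floor.  The default
reporting scale shifts each term by -log(1e-6) so scores are
non-negative (0 = completely off-distribution, ~13.8 = every descriptor
in its modal bin); the postfilter cutoff of 2.8 operates on this scale.
A raw (unshifted, always <= 0) scale is available as a switch.  Molecules
matching any pattern of the editable undesirable-SMARTS catalogue score
exactly 0.  The structural-alert descriptor uses a small bundled
catalogue of reactive/toxicophoric SMARTS; both catalogues are plain
text files users can replace.

**Similarity.**  Fragment similarity is the maximum Dice similarity of
2048-bit radius-2 Morgan fingerprints between the query's BRICS fragments
(attachment points stripped; a molecule with no BRICS bonds counts as one
fragment) and the reference.  Pharmacophore similarity is the Dice
similarity of Gobbi 2D-pharmacophore fingerprints; a molecule with no
perceivable features scores 0 with a warning.

**Pose penalty.**  For fragment-growth designs, the docking score of a
molecule is clipped to 0 when the docked copy of the reference fragment
(substructure-matched atoms, coordinates in the common receptor frame,
no re-fitting) deviates from the reference pose by more than a
configurable RMSD threshold (default 2.0 A, the conventional pose-match
criterion); a missing substructure match also clips.

**Interactions.**  An interaction profile is a typed contact list
(hydrogen bond, hydrophobic, pi-stacking, salt bridge, halogen) with
geometry and residue labels; any profiler producing this structure plugs
in, and a minimal geometric profiler (distance/angle rules against
labelled receptor sites) ships for tests.  The score sums residue-weight
x type-weight per contact; hydrogen bonds with donor angle < 135 deg *or*
hydrogen-donor distance > 2.8 A are classed weak and contribute at half
strength.  The two printed criteria are combined with OR because either
geometric defect alone marks a poor bond — an AND reading would grade a
short but badly bent bond as strong.  Contacts to residues without a
weight are ignored, so users reward only the residues they name.

## Docking backends

The engine contract is a molecule-to-(score, pose) map; scores keep the
engine sign convention end to end.  The external adapter speaks the
AutoDock Vina command-line interface (receptor/box/seed/exhaustiveness
flags), preparing ligands as a single embedded force-field-cleaned
conformer converted to PDBQT at pH 7.4 via openbabel.  The deterministic
mock backend — a negative Gaussian well in (molecular weight, logP) with
depth 12 kcal/mol centred at (320 Da, 2.5) — has a documented unique
optimum and smooth monotone degradation, which is what the RL smoke tests
need; it is the test oracle, not a physical model.  Batch scoring
preserves input order and isolates per-molecule failures.

## Reinforcement learning

Training maximizes expected terminal reward.  Each iteration samples a
batch (default 2,000 molecules full-scale; 60 in the smoke tests),
evaluates rewards, snapshots the policy, and then reuses the batch for
up to 10 gradient epochs of the PPO clipped surrogate

    mean_b min(r_b R_b, clip(r_b, 1-eps, 1+eps) R_b) + alpha * H_token

with sequence-level ratios r_b against the snapshot, default eps = 0.2
and alpha = 0.01, and the mean next-token entropy as the bonus.  No
learned value baseline is used (an optional batch-mean baseline exists
behind the raw reward by default being used as-is); the physics-based
scorer is the critic precisely to avoid reward-model exploitation.
Epoch reuse stops once the mean per-token KL divergence of the updated
policy from the snapshot (KL(new || old), token-position average)
exceeds 0.03.  Training stops when the mean token entropy drops below
50% of its trailing-10-iteration maximum — the quantitative reading of
"entropy starts to collapse" — or at the iteration cap.  One master seed
fans out to sampling, dropout masks and engine seeds; the per-iteration
trace (mean reward, entropy, KL, validity, epochs used) serializes to
CSV.

## Workflow

Postfilters are conjunctive and order-independent: no PAINS catalogue
match (RDKit A/B/C families), zero Lipinski rule-of-five violations,
Ertl synthetic-accessibility score <= 4.5 (the scale's customary
boundary between easy and hard syntheses; the printed sources do not fix
a value), drug-likeliness strictly > 2.8 on the shifted scale, and
optionally a confirmed interaction with named residues.  Consensus
rescoring takes >= 2 pluggable scoring functions and keeps molecules in
the intersection of every scorer's top fraction (default 10%, 1.5% for
the stricter MD pre-selection).

Distribution benchmarks use chained bases: validity = valid/sampled,
uniqueness = distinct/valid, novelty = unseen/distinct.  The
KL-divergence score is mean over the 13 descriptors of exp(-KL) between
corpus and generated histograms on shared supports (1 = identical
distributions).

Trajectory analysis consumes ligand coordinate frames (multi-frame PDB
via MDAnalysis, or arrays): each frame's receptor is superposed onto the
reference receptor by a best-fit (Kabsch) rotation, the transform is
applied to the ligand, and the RMSD against the starting pose is taken
without re-fitting the ligand itself.  A complex is stable iff mean
RMSD < 4 A *and* the mean per-frame hydrogen-bond count exceeds 1
("preserving more than one hydrogen bond" is read as a mean, not a
persistence criterion; both the threshold and the reading are
configurable).  Interaction frequencies are fractions of frames in which
each (residue, contact-type) pair occurs.

## Synthetic test conditions

The fixture corpus enumerates 12 drug-like ring cores (benzene,
pyridine, pyrimidine, furan, thiophene, pyrrole, naphthalene, saturated
5/6-rings with N/O) decorated with up to three substituents from a
21-group set, rejection-filtered to any requested molecular-weight
window; 5,000 unique molecules, seed 7, are the standard pretraining
condition.  Synthetic trajectories displace a pose linearly to a target
drift with optional Gaussian coordinate noise, giving closed-form
expected RMSD; synthetic interaction profiles place contacts at exact
per-residue frequencies.  The receptor stub is a hand-placed Gly-His-Glu
tripeptide (synthetic, not from any deposited structure).

These fixtures are deliberately simple: the corpus spans a few scaffold
families rather than medicinal-chemistry space, contains no charged,
hypervalent or stereo-annotated molecules, and its descriptor
distributions are narrower than a curated database's.  Passing tests
therefore demonstrate correctness of the machinery (representation
closure, gradient fidelity, reward plumbing, threshold behaviour,
RL improvement against a smooth oracle) — not that desk-scale training
reproduces full-scale chemistry, binding poses or the biological results
of any particular target campaign.

## Problem sizes

The default test/acceptance sizes — 5,000-molecule corpus, 64/128/128
generator, 20 pretraining epochs, 60-molecule RL batches for ~20
iterations, 10 RL seeds — were chosen as the smallest conditions under
which the qualitative behaviours (validity ~1, reward growth, entropy
decline) are stable and reproducible on a single CPU.
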