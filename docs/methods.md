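# Methods

This note records the models implemented in `photogen`, the choices made
where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Molecular graphs and the structural criteria

SMILES handling is delegated to RDKit: a molecule exists only if RDKit can
parse *and* sanitize the string (valence check, ring perception,
aromaticity). Malformed strings are returned as invalid-markers rather
than exceptions, because the generator's raw output is routinely invalid
and the valid fraction is itself a reported statistic. Strings containing
query/dative bonds (e.g. a literal `~`) sanitize but are not covalent
structures; they are counted as invalid.

The three structural rules used to identify long-wavelength candidates are
evaluated on the sanitized graph:

1. *polyatomic ring* — any SSSR cycle (all SMILES rings have ≥ 3 atoms);
2. *ring multi-unsaturation* — ≥ 2 non-single bonds (double, triple or
   aromatic) in the union of all ring bonds. Counting over the ring
   *system* rather than per ring makes fused rings pool their
   unsaturation; aromatic bonds count, so any aromatic ring satisfies the
   rule. Cumulated ring dienes count each double bond separately.
3. *ring heteroatom* — any non-carbon ring member (hydrogens cannot be
   ring members).

The *weakened* criterion is ≥ 2 of 3; for an acyclic molecule all three
rules are false by construction. The verdict is a function of the
canonical molecule, hence invariant to SMILES spelling.

## Character-level BPE tokenizer

The vocabulary seeds with a fixed 72-character alphabet — upper- and
lower-case element letters used by SMILES, digits, and structural
punctuation — shipped as an explicit constant (`SEED_ALPHABET`): the exact
72 symbols are this package's choice, made once for test stability, since
only the *count* is externally fixed. Characters observed in a corpus
outside the alphabet are appended after it. Merges are learned by
standard BPE pair counting over whole SMILES lines (no intra-line word
splitting), capped at 1000 by default; frequency ties break
lexicographically on the (left, right) pair, making training deterministic
in the corpus multiset. Pairs occurring only once are not merged.
Multi-character element symbols (`Cl`, `Br`) begin as two characters and
are acquired as merges — the defining property of character-level (vs
byte-level or atom-regex) tokenization. Four specials (`<pad>`, `<bos>`,
`<eos>`, `<unk>`) precede the alphabet in the id space. Encoding applies
merges in rank order; decoding concatenates token strings and drops
specials, so round-trip identity holds for any string over the alphabet.

## The decoder

`GptLM` replicates the GPT-2 block: pre-norm residual blocks, causal
multi-head attention, GELU (tanh form) MLP with inner dimension 4×d,
learned absolute position embeddings, final layer norm, and an output head
tied to the token embedding. With vocabulary 1072 (72 seed + 1000 merges),
d = 512, 8 heads, 4 blocks and 512 positions the trainable-parameter count
is exactly 13,421,568 (13.4 M); a closed form is cross-checked against
tensor enumeration in the tests. Specials beyond 1072 reuse reserved seed
slots in the replica configuration.

Forward *and* backward passes are hand-written in NumPy and verified
against central finite differences to ≤ 1e-6. The same backward engine
serves two gradient routes: mean token cross-entropy for causal-LM
training, and weighted sums of per-sequence log-probabilities for the
preference objectives (the route receives d loss/d logp per sequence and
pushes `w · (onehot − softmax)` through the cached activations).
Default dtype is float64 — models here are small and exact gradient checks
are worth more than speed.

Training uses AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay 0.01
applied to matrices only) with cosine annealing from 5·10⁻⁴ at step 0 to
5·10⁻⁸ at the final step. The reference schedule is 6 epochs at batch 128
and maximum sequence length 512; tests and the examples run scaled-down
models (d = 32–64, 1–2 blocks) and corpora of 80–150 molecules, which the
package treats as its standard desk-scale configuration. Over-length
sequences are truncated with a counted warning.

Sampling is seeded ancestral sampling (temperature 1.0, no top-k/top-p
truncation by default — configurable) from `<bos>` until `<eos>` or the
position limit, implemented with a per-block key/value cache that is
verified to match the full forward pass exactly.

### Low-rank adapter

The adapter follows standard LoRA practice: rank-8 factors on the
attention query and value projections, scaling α/r with α = 16, A
initialized N(0, 0.02²) and B at zero so the adapter starts as the
identity. `finetune_clm(trainable="adapter_only")` and `rlhf_finetune`
update only these tensors; the frozen base is fingerprinted (SHA-256 over
all base tensors) and asserted unchanged in tests.

## Excitation-energy model

The Coulomb matrix uses the standard convention: 0.5·Z^2.4 self-terms,
Z_iZ_j/d_ij pair terms with distances in Bohr, rows/columns sorted by
descending row norm, zero-padded to 23 atoms (the QM7b maximum; the
synthetic experiments pad to 25 because MMFF-relaxed fixtures with
explicit hydrogens can slightly exceed 23). Sorting makes the descriptor
invariant to input atom order; it is invariant to rigid motion by
construction. The feature vector is the flattened upper triangle
(276 values at 23 atoms).

The regressor is an sklearn-style estimator wrapping `sklearn.svm.SVR` on
per-feature z-scored inputs (standardization statistics are stored in the
fitted model and reused at prediction). `fit` performs the 80:20
train/test division internally (seeded) and records train MSE, test MSE
and held-out R². Grid search evaluates every configuration and selects
the minimizer of **train MSE + test MSE** — the combination rule is this
package's explicit choice, since only "both sets" is externally specified.
The selected configuration of record is rbf, C = 80, γ = 0.84; the SVR
tube ε defaults to 0.1. Wavelengths come from λ = 1239.84193/E.

Coordinates for arbitrary generated SMILES come from a provider contract:
the default provider embeds with ETKDGv3 under a fixed seed and relaxes
with MMFF; embedding failures are skipped and counted. The QM7b reader
instead returns the stored Coulomb matrices directly (property-column
index and energy unit are configuration, not hard-coded, because the
container does not name its columns).

## Screening metrics

QED is computed with RDKit's reference implementation of the published
desirability-function metric using the published mean weights (the
implementation's default variant) — this variant reproduces the reference
value 0.57 for the top-ranked molecule `OC1CC1OC(C)C`; the unit-weight
variant gives 0.62 and is not used. SAscore uses the published
Ertl–Schuffenhauer algorithm and fragment-score table shipped inside the
installed RDKit distribution, so values are pinned to that distribution;
fragment-table revisions move scores in the third decimal (the conjugated
alkene `C=CC=NSN=C` scores 5.538 here against a printed reference of
5.537). Band boundaries are left-closed/right-open on
{200, 400, 750, 2000} nm. QED ranking breaks ties on canonical SMILES for
determinism; SAscore triage is a configurable closed score window (the
documented example window being [5.47, 5.92]).

## Preference alignment

Feedback construction partitions criterion verdicts into weakened-pass
positives and zero-criteria negatives; molecules satisfying exactly one
rule are excluded from both datasets (they are neither recommended nor
clearly rejected). The binary dataset is always |positives| + |negatives|.
Preference pairs cycle seeded-shuffled positives over the negatives so
each negative appears exactly once; prompts are `<bos>`-only because
generation is unconditional.

Sequence log-probabilities are sums over completion tokens, not
length-normalized — except the CPO anchor term, which is the per-token NLL
of the chosen completion (weight 1.0 by default, 0 recovers the pure
sigmoid form). All three objectives use β = 0.1 and sigmoid shape by
default:

* DPO: −log σ(β[(logπ(c) − logρ(c)) − (logπ(r) − logρ(r))]) against a
  frozen pre-fine-tune reference ρ;
* CPO: reference-free −log σ(β[logπ(c) − logπ(r)]) + w·NLL(c)/|c|;
* KTO: v = w_D σ(β(r − z₀)) for desirable and w_U σ(β(z₀ − r)) for
  undesirable examples with r = logπ − logρ; loss = mean(w − v). The
  reference point z₀ is the batch mean of r clamped at ≥ 0 and detached
  from gradients. With `<bos>`-only prompts the mismatched-completion
  estimator of the original formulation degenerates (there is no prompt
  to mismatch), so the batch-mean form is used.

All losses equal ln 2 (or value 0.5 for KTO) in their zero-margin cases
and are verified against scalar arithmetic oracles and finite differences.
Fine-tuning updates the adapter only; DPO margins are tracked and increase
on fixtures.

## Synthetic data: what it emulates, what it does not

The generator assembles molecules from three template families —
heteroaromatic cores (all three rules hold), saturated carbocycles
(rule 1 only) and acyclic amines/alcohols/chains (no rule holds) — with
randomized substituents, parsing every candidate so emitted SMILES are
valid by construction. The planted energy is

    E[eV] = 12.0 − 0.55·(unsaturated ring bonds) − 0.45·(ring heteroatoms)
            − 0.12·(heavy atoms) + N(0, σ²),   clipped to [4.13, 12.41],

with σ = 0.3 eV by default. The coefficients are fixed once and versioned
here; they give criterion-positive molecules strictly lower noiseless
energies than negatives (the qualitative physics of conjugation and
heteroatom lone pairs) and a learnable structure–energy map.

What passing tests show: the pipeline's mechanics are correct — BPE
round-trips, gradients are exact, DPO/CPO/KTO move probability mass toward
preferred structures, the Coulomb-matrix/SVR stack recovers a planted
signal (held-out R² > 0.5 at n = 500, σ = 0.3 eV). What they do not show:
chemical realism of generated candidates, accuracy against quantum-
chemistry excitation energies (no electronic-structure computation is
performed anywhere; the shipped 17-row wavelength table is treated as
given input data), or transfer of alignment gains to real preference data.
Template-based corpora have far lower structural diversity than QM7b, so
absolute validity and enrichment numbers on fixtures are not predictions
for real corpora.

## Numerical and interface choices

* Determinism: every stochastic component (init, batching, sampling,
  pairing, embedding) takes an explicit seed; two runs with one seed are
  bit-identical.
* Checkpoints serialize config + all tensors to a `.npz` archive and
  reload bit-exactly.
* The workflow CLI rejects unknown config keys; stages resume from
  existing artifacts unless explicitly re-requested.
* Estimator shape: the excitation predictor follows scikit-learn estimator
  conventions (composable with sklearn model selection); the generative
  model and alignment trainers are not fit/predict-shaped and keep a
  trainer-style interface.
* Known limitations: no stereochemistry or tautomer handling in
  comparisons; single conformer per molecule; the quantum-kernel SVR
  variant is out of scope (interface accepts only classical kernels); no
  PubChem-scale pre-training — "pre-training" here means training on
  whatever corpus is supplied.
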