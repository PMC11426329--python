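# motifprofiler

Statistical structural profiles of RNA 3D motifs.

Recurrent RNA loop regions — hairpins, internal loops and multi-loops such
as the kink-turn, sarcin–ricin or GNRA families — are held together by
conserved non-Watson–Crick base pairs, yet individual instances of one
family vary in both sequence and interactions.  `motifprofiler` summarizes
a group of motif instances in a single *structural profile*: for every
position a frequency map of nucleotides (and gaps), and for every position
pair frequency maps of the observed Leontis–Westhof base pairs and base
stackings, together with the break points separating loop strands and the
motif count MC.  A profile can then be used as a query to scan RNA chains
for further instances of the family, ranked by alignment score and z-score.

## Method

Two profiles X and Y are aligned by a clique-anchored profile-to-profile
alignment.  The total score is

    S(P) = Σ_(i,j) { S_BP(i,j) + S_STK(i,j) } + Σ_i S_N(i) + gap penalties

where each matched interaction cell or column contributes the weighted
score

    S = (1/m) Σ_a (1/n) Σ_b Count(e_b^Y) · M(e_b^Y, e_a^X)

over its m X-side and n Y-side entries, with M an 18×18 isostericity-based
base-pair matrix, a stacking matrix or a nucleotide matrix (counts are
normalized by MC^Y by default).  Candidate matchings of interaction cells
form a compatibility graph whose edges mark mutually consistent matchings
(equal relation groups — juxtaposing, juxtaposing-shared, crossing,
enclosing, enclosing-shared-left/right — on both sides); every clique is a
consistent anchor set, and a branch-and-bound search (using the k(k−1)/2
edge bound) finds the clique whose anchored extension — dynamic-programming
sequence-profile alignment of the unanchored stretches, never bridging
break points — maximizes S(P), over every strand orientation of Y.

A family profile is built under a greedy guide tree: all instances start as
single-motif profiles, the best-scoring pair is merged (counts summed,
gap counts added for unaligned columns), and the loop repeats until one
profile remains; large inputs are reduced in chunks first.  Search wraps
every candidate loop of a chain as a single-motif profile, scores it
against the family profile, and reports z = (s − μ)/σ relative to the
profile's own members.

## Worked example

```python
import motifprofiler as mp

M = mp.load_matrices()                                  # packaged defaults
fam = mp.sample_family(mp.KINK_TURN_LIKE, 5, seed=42)   # synthetic family
prof = mp.build_profile(fam, M)
stats = mp.calibrate(prof, fam, M)
print(f"profile: MC={prof.mc}, {prof.length} columns, {len(prof.bp)} bp cells")
print(f"calibration: mu={stats.mu:.2f}, sigma={stats.sigma:.2f}")

chain = mp.plant_in_chain(mp.sample_family(mp.KINK_TURN_LIKE, 3, seed=7), 7, seed=8)
hits = mp.search_chains(prof, stats, [chain.loops], M)
for h in hits[:5]:
    print(f"{h.rank:>4}  {h.motif_id:<20} {h.score:8.2f} {h.z:7.2f}")
```

prints

```
profile: MC=5, 12 columns, 6 bp cells
calibration: mu=58.10, sigma=4.18
   1  kink_turn_like#1        61.50    0.81
   2  kink_turn_like#3        59.50    0.34
   3  kink_turn_like#2        44.50   -3.26
   4  DECOY#1                  1.50  -13.55
   5  DECOY#3                  1.00  -13.67
```

The profile of five noisy kink-turn-like instances spans 12 columns with
six base-pair cells; all three family members planted in the chain outrank
every random decoy, and their z-scores place the first two inside the
family's own score range (positive z) while the decoys sit far outside.

The same pipeline is available from the shell:

```sh
motifprofiler synth family --template kink_turn_like -n 5 --seed 42 -o fam/
ls fam/*.loop > motifs.txt
motifprofiler build -i motifs.txt -o fam.pfl          # + fam.pfl.tree
motifprofiler draw -p fam.pfl -o fam.svg
motifprofiler synth chain --template kink_turn_like -n 3 --decoys 7 --seed 8 -o chain/
motifprofiler search -p fam.pfl -c chain/ -m fam/ -o hits.tsv
```

Profiles are written as plain-text `.pfl` files (sequence profile,
base-pair profile, stacking profile, break points, motif count, entries
sorted by frequency); `draw` renders the filtered profile as SVG.

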