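# Methods

## Scope and data model

`ribodigest` models the computational side of endoribonuclease-based
LC–MS/MS characterization of IVT mRNA. Its inputs are transcript
sequences (FASTA, RNA or DNA alphabet; T is read as U, IUPAC ambiguity
codes are rejected with their position) and deconvoluted MS1 peak lists
(delimited text, one neutral monoisotopic mass + intensity per row).
Raw-spectrum processing — charge deconvolution, deisotoping, adduct-ion
handling — is upstream of this package and out of scope; so is MS/MS
database searching (a fragment-ion mass calculator is provided for
annotation only).

Sequences are tuples of monomer codes. Canonical A/C/G/U plus eight
modified uridines are built in (Ψ, m1Ψ, mo5U, m5U, Um, m5Um, s4U, D);
further monomers can be registered from a YAML table (code → elemental
formula, canonical base, 2′-O-methyl flag). A substitution profile maps
canonical bases to replacement codes transcript-wide (e.g. all U → m1Ψ),
mirroring how substituted IVT reactions replace an entire NTP.

## Mass chemistry

All masses are neutral monoisotopic masses computed from integer
elemental compositions over C/H/N/O/P/S with an embedded standard
atomic-mass table. A linear oligonucleotide with 5′/3′ hydroxyls is the
sum of its nucleoside compositions plus (n−1)·(HPO₃ − H₂O) for the
phosphodiester linkages; terminal groups and cap adducts are composition
deltas relative to hydroxyl (cyclic 2′,3′-phosphate = HPO₃ − H₂O;
m7Gppp cap = m7G nucleoside + 3·HPO₃ − H₂O; the m7GpppNm dimethyl
variant adds one further CH₂, folding the cap-adjacent 2′-O-methyl into
the adduct delta — equivalent by mass to a monomer substitution and
simpler to configure). Internal consistency (condensation additivity,
terminal deltas, complementary fragment-ion sums) is asserted to
1 × 10⁻⁶ Da; the test suite cross-checks every nucleoside mass against
pyteomics as an independent oracle.

"Same mass" questions — isomer detection, uniquely-mappable products —
are decided on exact composition keys (element-count tuples including
termini), never on floating-point equality, so Ψ/U compare equal by
construction.

Fragment ions follow the standard nucleic-acid backbone nomenclature
(a-B, a, b, c, d from the 5′ side; w, x, y, z from the 3′ side), derived
from prefix/suffix compositions so that cᵢ + y₍ₙ₋ᵢ₎ = precursor + H₂O
holds identically.

## Digestion

An enzyme is a set of cut contexts: upstream/downstream patterns of
canonical bases anchored at the scissile bond, plus a per-modification
cleavability map (`full` / `reduced` / `none`). `reduced` sites are
treated as cleavable for site finding — the package models site
presence, not kinetics — while `none` blocks the bond (e.g. hRNase 4 at
2′-O-methylated uridines, consistent with the 2′,3′-cyclic-phosphate
mechanism; MC1 at m1Ψ). mo5U is marked fully cleavable by hRNase 4:
fully mo5U-substituted transcripts digest normally in practice.

Complete digestion partitions the transcript (a structural invariant the
suite property-tests); missed-cleavage products are concatenations of
1..k+1 adjacent complete fragments, annotated with the dinucleotide
context of each skipped site. Coordinates are 0-based half-open
internally and in machine outputs.

Terminal chemistry: internal products receive the enzyme's default
product termini — hydroxyl/hydroxyl for the hRNase 4 + T4 PNK workflow
(the phosphatase homogenizes 2′,3′-cyclic and 3′-phosphate ends),
5′-OH/3′-phosphate for RNase T1 — while transcript-terminal products
inherit the molecule's own ends (hydroxyl unless a cap state is under
investigation, which the cap-search workflow owns).
`terminal_variants` enumerates the {cyclic-P, 3′-P, OH} species mixture
for phosphatase-free digests.

MazF's bond within ACA and Colicin E5's placement are shipped as the
literature convention (5′ of the first A; between G and U) and remain
configurable through the enzyme YAML, as does Cusativin's
no-cut-between-consecutive-C refinement (the shipped default is plain
C-specific).

## Coverage prediction

Coverage uses the complete digest only (missed cleavages enter only the
experimental-matching paths), products of 4–40 nt — a window practical
for both intact-mass and fragmentation analysis. Products whose sequence
occurs at multiple loci are excluded; among the retained set, products
with a unique composition key are uniquely mappable, the rest isomeric.
Uniqueness is evaluated within one transcript's digest, not across a
database. Coverage is the fraction of positions under the union of
retained intervals (identical to summed lengths for complete digests;
the union definition is used everywhere for safety with missed
cleavages). Poly-A tails are not special-cased: the input sequence
defines the denominator.

## MS1 matching and experimental coverage

Matching records every (peak, product) pair within the ppm tolerance
(computed against the theoretical mass; 10 ppm and ≤1 missed cleavage by
default), by binary search over product masses, with results independent
of input order. Peak intensities matching one product sequence are
summed. For experimental coverage each peak is assigned to its closest
product by |ppm|; exact ties (true isobars or one sequence at several
loci) are unplaceable and contribute nothing, except that ties differing
only in missed-cleavage count resolve to the fewest missed cleavages.
Under this closest-match rule a noiseless, fully detected simulation
reproduces the predicted uniquely-mappable coverage exactly (asserted in
the suite). A replicate filter supports "detected in at least k
independent digestions" semantics (default k = 1).

The multiplexed-pool report computes per-oligo log2 fold intensity
change (enzyme vs no-enzyme control; zero-control oligos are flagged,
not crashed on) and bins single-cut product intensities by terminal
nucleotide, normalised to the number of possible sites per base.

## Fingerprinting

The fingerprint product set per transcript is the complete digest,
4–40 nt, one entry per distinct sequence (repeated fragments would make
"fraction of theoretical products" ill-defined), isomeric products
included. identity score = detected fraction × explained-intensity
fraction; a peak may explain several transcripts simultaneously (no
intensity apportioning), which is what makes low-specificity enzymes
produce higher score backgrounds. S/N uses the population SD (n
divisor); at database scale the difference from the sample SD is
negligible. Missed cleavages are excluded from fingerprint scoring.
Ranking is deterministic with ties broken by transcript id. The default
fingerprint tolerance is 5 ppm.

## Cap search

5′-terminal products (anchored at position 0, up to 2 missed cleavages
by default — a CLI flag raises this to 3 for workflows that prefer it)
are computed with a 5′-hydroxyl baseline, and each candidate adduct
(p, pp, ppp, m7Gppp, m7Gppp+2′-O-methyl) is added as a mass delta before
searching the peak list. A capped preparation shows terminal products
shifted by Gppp + 2·CH₂ relative to the uncapped control. Absolute
capping-efficiency quantitation is out of scope.

## Synthetic data

The generator defines the conditions under which the package is tested:

* **random_transcript / decoy_database** — i.i.d. uniform A/C/G/U by
  default (configurable frequencies), decoy lengths uniform on
  500–2000 nt; these stand in for a reference transcript database.
  Real mRNA has codon structure, biased composition and repeats, so
  absolute coverage numbers on random sequences do not transfer to real
  constructs — the directional comparisons (UR- vs G-specific enzymes)
  and all pipeline invariants do.
* **dinucleotide_pool** — all 16 dinucleotides, each between poly-A
  flanks with staggered lengths so every intact oligo has a distinct
  mass. In-silico hRNase 4 digestion reproduces the expected pattern:
  every U-containing oligo is cut except the UC-only one.
* **modified_u_pool** — eight oligos in a U-free poly-AG backbone, one
  N*·A site each (N* ∈ {U, Um, Ψ, m5U, m5Um, s4U, D, m1Ψ}); the
  2′-O-methylated members are refractory to hRNase 4 under the shipped
  cleavability map.
* **simulate_peak_list** — per-product Bernoulli detection
  (default 0.9), Gaussian relative mass error (default σ = 1 ppm),
  log-normal intensities (median 10⁶, σ = 1 in log space), Poisson
  contaminant peaks uniform over the observed mass range (default 5 per
  100 products). Defaults sit well inside the 5/10 ppm matching
  tolerances and are deliberately unexceptional; they model neither
  retention time nor detectability differences by length or charge.

All generators are deterministic under their seeds.

## Problem sizes and numerical choices

The fragment-length convergence check uses a single 10⁶-nt random
transcript (P(cut) = 1/8 per bond ⇒ mean length → 8 nt, asserted within
2%); coverage medians use 200 transcripts; spike-in recovery uses 100
simulated runs against a 200-decoy database with a 1000-nt target.
Closest-match ties use an absolute 10⁻⁹-ppm epsilon; internal mass
assertions use 10⁻⁶ Da; matching-window bounds are computed exactly from
the signed-ppm definition before the per-pair check.

## Known limitations

* Cleavage is modelled as site presence: no kinetics, no secondary-
  structure effects, no enzyme-concentration dependence.
* Two published construct-specific checks (fLuc coverage levels and
  construct lengths) need the construct sequences supplied by the user
  (`tests/data/constructs.fasta`); they are not redistributable here and
  random surrogates cannot stand in for construct-specific composition.
* The MS/MS side is annotation-only (fragment masses); no spectrum
  scoring or FDR machinery.
* Na⁺/K⁺ adducts and isotope distributions of MS1 peaks are not
  simulated or matched.
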