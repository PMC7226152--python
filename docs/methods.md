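# Methods

## Mass model

All arithmetic is monoisotopic. A residue contributes its glycosidically
linked (net-of-one-water) formula: HexNAc C8H13NO5 = 203.07937 Da, Hex
C6H10O5 = 162.05282, Fuc/dHex C6H10O4 = 146.05791, NeuAc C11H17NO8 =
291.09542. Atomic masses carry at least eight significant decimals; the
proton is 1.007276 Da and the sodium cation 22.98922 Da.

Aglycones: a free reducing end adds one water; a benzyl glycoside adds
water plus C7H6 (+90.04695 Da over the free sugar — the reporter scaffold
secreted by cells fed peracetylated benzyl-GalNAc); a Ser/Thr aglycone adds
nothing, because the glycan replaces the hydroxyl hydrogen and the reported
quantity is a modification *delta* (HexNAc1 → +203.079, the Tn antigen).

Permethylation replaces every exchangeable hydrogen with a methyl group,
+14.01565 Da per site. Sites are counted structurally per residue: free
hydroxyls not consumed by a glycosidic bond or the aglycone, one amide N–H
per HexNAc/NeuAc, and one carboxyl methyl-esterification per NeuAc (the
ester is not optional under exhaustive permethylation and is required to
reproduce observed sialoglycan masses). Positions are validated against
each residue's linkable valence (HexNAc 3/4/6, Hex 2/3/4/6, Fuc 2/3/4,
NeuAc hydroxyls 4/7/8/9, anomeric C2); topologies with unknown (`?`)
linkage positions require an explicit free-hydroxyl override before site
counting.

Reported ions are singly protonated. This choice reproduces every
one-decimal glycome m/z the package prints (572.3, 746.4, 933.5, 729.4,
1021.5, 1195.6, 1556.8) and is therefore the default; sodium adducts
remain available through `AdductSpec`.

## Fragment enumeration

Glycosidic cleavages produce B/C (non-reducing) and Y/Z (reducing) ions;
cross-ring cleavages produce A/X ions labelled by the pair of broken ring
bonds (0 = O5–C1 … 5 = C5–O5). Masses come from the fragment's explicit
atom content: a B ion is the detached subtree as an oxocarbenium, Y is the
complement with the glycosidic oxygen retained as a hydroxyl (the methyl
"scar" appears automatically, because a linked position was never
methylated), C = B + H2O and Z = Y − H2O. Cross-ring cleavages partition
the ring atoms with no hydrogen transfer; the arc lost by an X ion carries
its substituents, including whole child subtrees. The identities
mz(B) + mz(Y) = mz([M+H]⁺) + 1.007276 and the A/X analogue hold exactly by
construction and are enforced in tests.

Cross-ring support covers the six-membered pyranose rings of Hex, HexNAc
and Fuc for the bond pairs 0,2 / 0,3 / 1,3 / 2,4 / 3,5 / 2,5 — the set
that separates type-1 from type-2 chains. Sialic-acid rings are not
cleaved (their diagnostic value here is nil and general A/X enumeration is
unbounded). Double cleavages combine exactly one glycosidic Y/Z loss with
one cross-ring event (e.g. the Z/3,5X ions); fragments retaining a benzyl
aglycone are additionally emitted with the tag lost as benzyl alcohol
(−108.0575 Da). The enumeration is verified fragment-by-fragment against
an independent brute-force oracle that builds the molecule as an explicit
atom graph and partitions it at the cleaved bonds (tests/atomgraph.py);
agreement is ≤1 mDa over hundreds of random topologies, the residual being
the electron-mass convention for oxocarbenium ions.

## Isomer discrimination

SLeA and SLeX are isobaric decorations of a GlcNAc (NeuAc–Gal plus Fuc;
β1-3/α1-4 vs β1-4/α1-3). Both candidate topologies are built on the shared
benzyl core — by default the core-2 6-arm
`Gal(b1-3)[epitope-GlcNAc(b1-6)]GalNAc`, configurable to an extended
core-1 3-arm, since MS1 composition cannot distinguish the arms — and
fully enumerated. Diagnostics are fragments whose m/z lies farther than
the matching tolerance from every fragment of the other isomer; at the
0.5-Da ion-trap default this yields 13 SLeA-only and 16 SLeX-only masses.
A verdict requires at least `min_diagnostics` (default 2) matches for the
winner and strictly fewer for the loser; ties and under-supported spectra
return `undetermined`. The single most telling ion is the SLeX Z/3,5X
fragment through the epitope GlcNAc at a theoretical 653.33 Da — absent
from the SLeA set, and within the 0.8-Da accuracy of unit-resolution
ion-trap readings near 653.9. Matching is absolute-Da throughout (0.5
default, 0.8 maximum sensible), never ppm, reflecting linear-ion-trap CID
product spectra.

## Quantification

Relative abundance is each glycan's share of the summed signal of one cell
line's glycome, in percent. Isomer fractions integrate
retention-time-resolved peaks sharing one m/z (trapezoidal rule over XIC
points, or areas supplied directly — no peak-shape model is imposed) and
apportion by per-peak isomer calls; undetermined peaks are excluded with a
logged count. Clustering preprocessing replaces zeros column-wise by half
the smallest positive value, applies the natural log, and autoscales each
glycan to mean 0 / SD 1 (ddof = 1); constant columns are excluded and
reported. Clustering itself is out of scope.

## Identification-list set algebra

Records are keyed case-insensitively by accession (gene symbol as
fallback) — identifications from different gel bands collapse onto this
key. The "confirmed O-SLeA" filter keeps proteins with at least one
SLeA-terminated glycopeptide in *any* cell line (a global filter, matching
how evidence accrues across lines); the E-selectin filter requires
pulldown identification in each line considered. Venn summaries report all
2^k − 1 exclusive regions, which must sum to the union — enforced against
a brute-force inclusion–exclusion oracle in tests.

## Target score

Nine additive variables, total 0–15: (i) healthy-cell location other than
membrane (1); (ii) cancer-cell membrane location (1); (iii) healthy
gastric epithelium plasma-membrane expression negative/low/moderate/high →
3/2/1/0; (iv) gastric-cancer expression → 0/1/2/3; (v) poor-prognosis
association (1); (vi) brain-exclusive expression (1); (vii) no lymphoid
plasma-membrane expression (1); (viii) no gamete expression (1); (ix)
healthy-tissue plasma-membrane index none/low/moderate/high → 3/2/1/0.

Two points were genuinely open and are resolved as follows, both
configurable: (vi) is read literally, so proteins absent from the brain
score 0 (only brain-exclusive expression is rewarded, as a proxy for
blood–brain-barrier-protected off-targets); (ix) maps the *maximum*
plasma-membrane expression level across surveyed healthy tissues excluding
the gastric epithelium (already variable iii). Ranking is by descending
total, ties broken by the healthy-sparing component (iii)+(ix), then
lexicographic protein id — a stated, deterministic rule. Exhaustive
single-field perturbation over the full 6144-record vocabulary lattice
verifies bounds and monotonicity.

## Synthetic data

All generators draw from `numpy.random.Generator` (PCG64) seeded with an
explicit integer; identical parameters and seed give identical outputs.

*Spectra*: every theoretical fragment in the scan range, jittered
N(0, 0.2 Da) — the empirical spread of unit-resolution ion-trap readings —
with log-normal intensities around 10⁴ counts, plus 20 uniform noise peaks
an order of magnitude weaker; the precursor is the exact [M+H]⁺. Not
modelled: isotope envelopes, peak shapes, intensity structure of real CID
(so passing recovery tests shows tolerance and diagnostics logic, not
intensity-aware scoring).

*Identification tables*: three cell lines at the study scale (987/467/798
distinct proteins), a planted 22-protein core present in every line and
both strategies with SLeA evidence, explicit pairwise-shared (6%) and
triple-shared (5%) pools, and per-protein strategy membership
both/IP-only/pulldown-only at 0.54/0.36/0.10 — giving the observed ~60%
dual-identification rate among IP identifications. Triple-pool proteins
never carry SLeA evidence, so the planted core is by construction the only
fully shared evidence-positive set; real data offer no such guarantee,
which is why the filters, not the generator, are the object under test.
Non-core SLeA evidence is Bernoulli(0.2) per protein per line.

*Annotation panels*: 22 records (the common-core size), vocabulary
frequencies reflecting that most proteins are broadly expressed in healthy
tissue, plus one planted maximal nucleolin-like profile (nuclear in
health, membrane in cancer, invisible in healthy tissues).

## Numerical and scale choices

Test and acceptance workloads are sized to finish in seconds while keeping
estimates meaningful: 500 random topologies for the complementarity/oracle
sweep, 200 spectra per isomer for recovery, 100 random designs each for
the Venn and ranking checks. The false-match ceiling for noise spectra is
not a tuned constant: it is derived per run as the m/z-axis coverage of
the ±tol fragment intervals plus three binomial standard errors.

## Known limitations

- Charge 1 positive mode only; no isotope patterns; no glycopeptide
  backbone (b/y) fragments.
- Cross-ring ions are limited to the six tabulated bond pairs and to
  Hex/HexNAc/Fuc rings.
- The reported printed ion-trap readings are reproduced within 0.8 Da, not
  asserted as exact theoretical equalities — unit-resolution centroids
  carry that much systematic error by nature.
- The set-algebra module deduplicates by protein key and does not attempt
  protein inference from shared peptides or FDR control; it consumes
  already-validated identification lists.
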