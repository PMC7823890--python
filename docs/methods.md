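# Methods

## Scope and model

pefanet implements the computational side of a bioactivity-guided
metabolomics study of PEFA glycolipids: exact-mass arithmetic, a
combinatorial theoretical library, rule-based MS/MS annotation,
modified-cosine molecular networking, bioactivity correlation scoring,
group-origin analysis, and a synthetic-data generator that makes the whole
chain testable without instrument data. Feature finding (chromatogram
deconvolution, isotope grouping, alignment) is out of scope: the package
ingests a feature-per-spectrum MGF and a feature × sample area table, the
standard exports of MZmine-style preprocessing.

## Mass arithmetic

Monoisotopic atomic masses (Da): C 12 (exact), H 1.0078250319,
N 14.0030740052, O 15.9949146221, Na 22.9897692809; electron 0.0005485799.
Two adduct conventions are exposed. *ion-mass* (default) adds the charge
carrier's ionic mass (atom − electron) and is the physically correct m/z of
a singly charged cation; *atom-mass* adds the neutral atom. High-resolution
values in the glycolipid literature mix the two — sodiated calculated masses
typically carry the electron correction while protonated ones often do not —
so the convention is a parameter rather than a guess. Display rounding is
half-even to 4 decimals; full precision is kept internally.

## The theoretical PEFA library

A species is (polyol, polyol-acetyl count, chain length, C-3 substituent).
Mannitol (C6H14O6) admits 0–5 acetyls and arabitol (C5H12O5) 0–4, because
one hydroxyl is consumed by the ester bond. Chains default to the even
C10–C20 set and substituents to 3-hydroxy/3-acetoxy, giving
(6+5) × 6 × 2 = 132 species; 3-methoxy species are rare and opt-in.
Positional acetylation isomers are deliberately not enumerated — they are
isobaric and indistinguishable by these rules. Predicted fragments per
species: the acetic-acid-loss ladder (one 60.0211 Da step per acetyl in the
whole molecule), the residual acetylated-polyol ion after loss of the intact
free fatty acid (no additional water transfer; this reproduces the observed
residual ions within 2 mDa), and further acetic-acid losses from that
residual.

## Annotation

Candidates are selected by precursor match within 0.02 Da (the usual QToF
tolerance, also used for fragments). The acetyl ladder is counted greedily:
starting at the precursor, repeatedly step to the closest fragment within
tolerance of (current − 60.0211), each fragment usable once. Greedy-closest
is adequate because real ladders are sparse (steps are 60 Da apart while
tolerances are 0.02 Da), and it makes ladder length monotone non-increasing
as the tolerance tightens. The residual-ion table maps every
(polyol, acetyl count) to its sodiated m/z; the best fragment hit (smallest
|Δ|) assigns the head group. A candidate is retained only if
ladder ≤ its total acetyl count and any residual-ion hit agrees with its
head group and polyol acetylation; ties break by precursor error, then
fewest acetyls. Confidence is `full` with at least one fragment-level
evidence type, `precursor-only` with none, `none` without a precursor match.
Head-group ambiguity from the precursor alone cannot arise within the
default library (mannitol/arabitol pairs differ by CH2O, which no
combination of acetyl/chain steps reproduces), but the confidence tiers
still encode it defensively.

## Networking

Spectrum cleaning removes fragments within ±17 Da of the precursor and
keeps a peak only if it is among the 6 most intense within ±50 Da of its own
m/z (ties to the lower m/z for determinism). Modified cosine weights peaks
by √intensity, Euclidean-normalized per spectrum; candidate peak pairs match
directly or shifted by the precursor mass difference (a pair may qualify via
either route, never counted twice); the score is the exact maximum-weight
one-to-one assignment over candidate pairs, solved with the Hungarian
algorithm. Exact assignment was chosen over the common greedy heuristic:
filtered spectra carry at most a few dozen peaks, so exactness is free, and
it makes the score a well-defined maximum rather than an
implementation-dependent approximation (the test suite checks it against
brute-force enumeration, and against matchms where the two agree on the
optimum). Edges require cosine > 0.7 and ≥ 6 matched peaks. The published
workflow wording is inconsistent between "more than six" (network edges)
and "at least six" (library search); we adopt ≥ 6 for both, the common
convention, and expose the threshold. Edges then pass a mutual top-10 rule,
and any connected component larger than 100 nodes loses its lowest-cosine
edge (ties: lexicographically smallest node pair) until it fits; components
of size ≥ 2 are molecular families. Local reference-library search filters
reference spectra identically and applies score > 0.7, ≥ 6 matched peaks.

## Bioactivity scoring

Quant columns are TIC-normalized (each sample divided by its total area;
zero-total samples are an error), then each feature row is Pearson-correlated
with the activity of the shared samples (≥ 3 required). Zeros are data —
absence in a fraction is area 0 and participates in the correlation.
Zero-variance rows are excluded with a recorded reason rather than scored.
Features with r strictly greater than 0.5 are flagged; no multiple-testing
correction is applied (the score is a ranking heuristic, not a test).
A known property of normalize-then-correlate: when flagged features jointly
dominate the TIC of the active fractions, normalization compresses their
shares and can pull r below the threshold; with realistically many features
the effect is small, but it is visible on tiny tables.

## Synthetic data

The generator emulates a 31-fraction reversed-phase separation (the default
activity profile is a low baseline with a 40/75/90/60 % inhibition block
over four late fractions) with 40 PEFA features, 20 decoys, 2 blanks,
5 mDa m/z jitter, 5 noise peaks per spectrum at 5 % base intensity, and 22
activity-driven features (area = c·activity + N(0, 0.05·c), clipped at 0).
Fragment intensity profiles are a deterministic function of the species
descriptor — the way a compound's fragmentation pattern is reproducible on
an instrument — with the residual-polyol ion and first acetyl loss as base
peaks and the rest log-uniform in [0.1, 1]; only observed m/z values, not
intensities, are diagnostic in the annotation rules. Decoy precursors stay
≥ 0.05 Da from every library mass; 30 % of decoys are designated
contaminants present in blanks and across fractions. Non-bioactive,
non-contaminant features elute in a contiguous 2–6 fraction window with
log-normal areas. Each output stream draws from its own child generator
spawned from the master seed, and files are written with fixed numeric
formats, so equal seeds give byte-identical files.

What the generator does not emulate: isotope envelopes, multiple adducts
per compound, retention-time correlation structure, detector saturation,
co-eluting chimeric spectra, and intensity irreproducibility between runs.
Passing tests therefore demonstrate the correctness of the rules and scores
under the stated noise model, not instrument-grade performance on real
acquisitions.

## Problem sizes and numerics

Tests and the acceptance script use deliberately small instances — spectra
of ≤ 5 peaks for brute-force assignment checks (1,000 pairs), 20–40-feature
datasets over 20 seeds, a 120-node chain for capping — chosen so the full
suite completes in well under a minute while still exercising every rule.
Floating-point tolerances: mass arithmetic asserted to 1e-9 Da relative
identities and 4-decimal display equality; cosine scores to 1e-9; Pearson
to 1e-9 against the closed form. Degenerate inputs (empty spectra, empty
fragment lists, zero-intensity spectra, all-zero quant columns, empty
libraries) are defined errors or defined zeros, never NaNs.

## Known limitations

Annotation assumes sodiated precursors for PEFAs ([M+H]⁺ is supported by
the mass layer but PEFAs ionize overwhelmingly as [M+Na]⁺); chain lengths
are restricted to the configured even set; unsaturated or odd-chain fatty
acids and head groups other than mannitol/arabitol require extending the
library configuration; acetylation positions and stereochemistry are out of
reach of MS/MS by construction.
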