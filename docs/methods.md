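# Methods

## Model and conventions

**Bit conventions.** Bytes unpack most-significant-bit first. Messages are
segmented every 280 bits (56 five-bit groups); the final segment is
zero-padded and the original bit length recorded in the sidecar, so
reconstruction is exact. These conventions are frozen because every
downstream nucleotide depends on them.

**Dual-rule rotary table.** The constraints on the table — 16 codewords per
rule with G/C counts {1, 2}, first base fixed by bits 2–3, bits 4–5 mapped
injectively per (rule, first base) cell, no homopolymer above 3 nt — do not
determine it uniquely. `build_code_table()` therefore constructs one
canonical table deterministically: four entries exercised by the worked
transcoding example are pinned first (`11101→CAC`, `00100→TCA`, `00010→ATC`,
`11110→CTG`), and every remaining slot takes the lexicographically smallest
unused legal (base2, base3) pair. One extra constraint, `base2 ≠ base1`, is
imposed in every cell: no codeword then begins with a doubled base, which
provably caps runs at 3 across slice boundaries (the first base of a slice
is context-free, so without this a run of 4 could straddle a boundary). The
result is validated exhaustively at construction — 32 distinct codewords,
GC classes, injectivity, pins, and runs ≤ 3 over all 32×32 adjacent codeword
pairs — and shipped under the version tag `drrc-table-1`; sidecars record
the tag and decoding refuses a mismatch. The table is auditable as plain
text via `CodeTable.to_text()`.

**First-bit balancing.** The global leading-bit stream (one keystream for
the whole file; a single stored parameter triple then suffices) is checked
against the balance band *before* any XOR — an already balanced stream uses
zero iterations. Each subsequent trial XORs the *original* stream with the
next `len`-sized block of the continuing logistic orbit. This
non-cumulative protocol is what makes single-state storage invertible: the
recorded `x0_success` is the orbit state immediately preceding the
successful block, so decode regenerates that one block and XORs once.
Binarization thresholds at x ≥ 0.5 → 1 (the tie is a measure-zero event;
one branch had to be chosen). The orbit is computed in 64-bit floats and
`x0_success` is serialized via `repr` (17 significant digits), which
round-trips exactly through JSON on IEEE-754 platforms. Defaults: band
(0.40, 0.60); the tight band (0.49, 0.51) is selectable and is what pins
mean payload GC to 50% ± 1%; `max_iter` 10,000 with a hard error on
exhaustion (with ≥ 4 leading bits and a chaotic orbit this is effectively
unreachable).

**Oligo layout.** Core field order is index | payload | parity, 5′→3′,
flanked by two fixed 24-nt primers (50% GC, runs ≤ 2, mutually distant);
255 nt total. The index is encoded through the same dual-rule codec from a
25-bit word whose five leading bits are fixed to `01010` — decodable before
derandomization (which needs segments in order) and a cheap integrity check;
20 information bits address ~10⁶ segments (≈ 36 MB/pool). The RS parity is
computed over index + payload, so a corrupted index is repairable.

## Error correction

**Level 1 — resynchronization.** The read is classified by length (shorter
than 207 nt ⇒ deletion, longer ⇒ insertion); slices are scanned left to
right and at the first slice at nonzero Hamming distance from the
32-codeword set the single-base edit is applied (delete the slice's first
base, or insert the filler at its first position), the repaired slice is
skipped, and the scan continues — once per unit of length discrepancy, so
multiple indels are handled. A trailing fragment shorter than one slice
counts as an automatic nonzero-distance slice. The filler is a fixed `A`
rather than a random base: the repaired slice is sacrificial either way and
determinism simplifies testing. Because only 32 of 64 possible slices are
codewords, a frame shift may pass through a few accidentally-valid slices
before detection; the damage stays contiguous between the true error and
the repair point, and exhaustive single-indel scans in the test suite
verify that everything downstream of the repair realigns.

**Level 2 — Reed–Solomon.** Bases pack 2 bits each, MSB-first, 4 nt per
GF(2⁸) symbol (primitive polynomial 0x11d): the 183-nt message region packs
to 46 symbols (two tail pad bits), and 6 parity symbols serialize to exactly
the 24-nt parity field — the only standard construction fitting that
budget. Capacity is t = 3 symbol errors; symbols are 4-nt aligned, so a
single substitution costs one symbol and a resynchronized indel typically
1–2. Decoding computes syndromes (vectorized across the pool; clean reads
short-circuit), then Berlekamp–Massey, a Chien search over the shortened
positions, and a direct GF-linear solve for magnitudes, followed by a
syndrome re-check so failures are flagged rather than miscorrected.

**Channel convention.** "An x% error rate" is read per-sequence: each oligo
is independently corrupted with probability x and receives one error, its
type drawn 27:1 substitution:indel in mixed mode (indels split evenly).
The arithmetic forces this reading for the two-level stack as parameterized:
a per-base 2% channel would place ~4 errors on every 207-nt core, beyond
any 24-nt-parity RS code, while one error per corrupted oligo is well
within t = 3. A per-base mode is provided for study. Errors land in the
core only by default (primers are assumed recoverable by primer matching;
a full-oligo region option exists).

## Synthetic data

Inputs are uniform pseudo-random bytes from a seeded generator
(`channel.make_fixture`), size-matched to the reference experiments:
876,960 bytes (25,056 segments) for density and constraint statistics, and
2,316-oligo pools (2,316 × 35 bytes) for recovery sweeps. Uniform bytes are
the natural stand-in for compressed or mixed-format files; they exercise
every 5-bit group value and hence all 32 codewords. What they do not model:
biased or highly repetitive plaintexts (which only shift how many balancing
iterations are needed — the band guarantee is unchanged), synthesis
drop-out, strand breakage, coverage skew, or read-depth consensus; the
channel injects independent errors per oligo, not PCR-correlated ones. A
recovery rate measured here is therefore an in-silico channel figure, not a
wet-lab one.

## Experiment design and problem sizes

`run_experiment` encodes one fixture per configuration, then for every
(rate, replicate) draws an independently seeded corrupted pool and decodes
the *same* pool at each correction level, making the
none ≤ resync ≤ resync+RS comparison paired. Replicates default to 10 with
a deterministic seed schedule; results are tidy DataFrames with one row per
(rate, correction, replicate). Recovery is strict: an oligo counts only if
its full 280-bit payload is bit-exact; duplicate indices keep the copy that
passed RS; missing indices count as failures and the corresponding segment
is zero-filled in file reconstruction. The shipped acceptance script uses
2,316-oligo pools, 10 replicates, and a 1-MB corpus for constraint
statistics — sizes chosen to match the reference experiments while keeping
a full run around ten seconds on one CPU.

## Known limitations

- The constructed table satisfies every stated constraint and the four
  pinned entries but is not claimed entry-for-entry identical to any other
  realization of the scheme; pools must be decoded with the table version
  recorded in their sidecar.
- Indel repair sacrifices the corrupted slice by design; when detection
  lags several slices the residue can exceed RS capacity (~10% of single
  indels in exhaustive scans), which bounds indel-heavy recovery.
- The chaotic XOR provides obscurity, not audited cryptography.
- Keystream regeneration assumes IEEE-754 double arithmetic; exotic FP
  environments would need the keystream itself archived.
- Uncorrected indel-only sweeps are not a meaningful recovery metric under
  strict full-payload matching (a frame shift fails the whole oligo), so no
  headline figure is derived from them.
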