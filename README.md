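# nanofp

Structural descriptors and toxicity tooling for binary metal-oxide
nanoparticles described by plain XYZ files.

The package builds a fixed-layout **shell fingerprint**: bonds are deduced
from interatomic distances via covalent-radius cutoffs, atoms are split
into core and shell by a radial thickness band, and the vector counts the
local coordination structures found among shell atoms and shell bonds.
Around that core it provides:

* **Subcomponent search** — count appearances of a small labelled query
  structure (XYZ or GRF) in the shell's bond graph.
* **QSAR protocols** — leave-one-out linear regression (LDH-style
  endpoints) and stratified 10-fold logistic classification with
  training-fold minority oversampling, plus assembly of designs that
  concatenate tabular physicochemical features with fingerprint sections.
* **A generative model** — per-position log-linear regression that
  predicts a whole fingerprint from (metal, size) alone, for particles too
  large to build in 3D.
* **Synthetic fixtures** — spherical particles cut from idealised
  lattices (rocksalt MO, fluorite-type MO2, vacancy-ordered M2O3), an
  optimisation-like perturbation that raises surface-oxygen coordination,
  and planted-effect QSAR tables. Everything is testable offline.

## Fingerprint layout

For a maximum-bonds parameter `MAX` (write `W = MAX + 1`):

| section | slots | content |
|---|---|---|
| 1 | 6 | thickness (Å), MAX, particle size (Å), metal atomic number, shell O count, shell metal count |
| 2 | 2·MAX | `O(c)` / `M(c)`: shell atoms with total coordination `c ∈ [1, MAX]` |
| 3 | 2·W² | `O(x,y)` / `M(x,y)`: shell atoms with `x` O neighbours and `y` metal neighbours |
| 4 | 3·W⁴ | bonded pairs of typed environments: O–O, M–M and O–M blocks |

Canonical length: `6 + 2·MAX + 2·W² + 3·W⁴`. A second "positive-only"
arithmetic (`6 + 2·MAX + 2·MAX² + 3·MAX⁴`, e.g. 30 226 at MAX = 10) is
available through `fingerprint_length(..., convention="positive-only")`
for compatibility; the stored vector always follows the canonical layout.
Counting conventions (shell-shell bonds only; degree > MAX atoms excluded
from sections 2–4; symmetric pair blocks canonicalised) are documented in
`nanofp/fingerprint.py`.

## CLI

```sh
# fingerprint of a structure (thickness in Å; add --nm to pass nm)
nanofp fingerprint --in particle.xyz --thickness 5 --max 5 \
    --out particle.fp.txt --labeled-xyz particle.labeled.xyz

# subcomponent search (use a huge thickness to search the whole particle)
nanofp search --target big.xyz --query small.xyz --thickness 4
nanofp search --target big.xyz --query small.grf --thickness 1e6 --induced

# QSAR protocols over a CSV (last column = response)
nanofp predict --model ldh --data ldh.csv --size 30 --conc 100
nanofp predict --model toxclass --data tox.csv --folds 10 --seed 0

# structure-free fingerprint generation
nanofp fit-generator --structures Zn:10.5:p1.xyz --structures Zn:16.8:p2.xyz \
    --thickness 3 --max 6 --out gen.json
nanofp generate --generator gen.json --metal Zn --size 80 --out big.fp.txt

# synthetic fixtures
nanofp synth particle --lattice rocksalt --metal Zn --a 4.2 --diameter 18 --out p.xyz
nanofp synth dataset --n 100 --p 5 --kind logistic --out d.csv
```

`nanofp --help` lists everything. Exit codes: 0 success, 1 domain error,
2 usage error.

## File formats

* **XYZ** — line 1 atom count, line 2 comment, then `Symbol x y z` per
  atom (Å). Extra trailing columns are ignored on read.
* **Labelled XYZ** — XYZ plus a fifth `core`/`shell` column per atom.
* **GRF** (query graphs) — line 1 `N M`; then `N` lines `index element`;
  then `M` lines `i j` (0-based, unordered edges). Minimal by design and
  easy to hand-author.
* **Fingerprint text** — `#`-prefixed section-1 header, then
  `position value` lines for non-zero entries only; a dense labelled CSV
  export also exists.
* **Generator** — a single JSON file.

## Caveats

* Binary oxides only: one metal species plus oxygen.
* The synthetic lattices are idealised stand-ins with controllable
  stoichiometry and coordination statistics; they are not
  crystallographically faithful to anatase/rutile/corundum.
* Bond inference is a distance cutoff (`tolerance × (r_i + r_j)`,
  default tolerance 1.15, Cordero radii shipped as
  `nanofp/data/covalent_radii.csv`); pick metal/lattice-constant pairs
  whose metal–metal spacing exceeds the cutoff when generating fixtures.
* Shell statistics count bonds with both endpoints in the shell;
  boundary-crossing bonds are excluded.
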