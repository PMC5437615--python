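# graphcoords

Offset-based coordinate systems and unambiguous interval representations
for graph-based reference genomes (sequence graphs with alternative
loci), plus the graph-construction procedures needed to build such
graphs from assembly-style inputs.

## What it does

- **Sequence graphs** (`graphcoords.graph`): DAGs of DNA blocks with
  designated main (chromosome) paths; JSON and GFA1 export; path
  enumeration and sequence spelling.
- **Coordinate systems** (`graphcoords.coordinates`): two region-path
  partitionings — *hierarchical* (one region path per chromosome, one per
  alt locus; stable under updates) and *sequential* (main paths split
  wherever an alternative starts or stops; spatially coherent). Position
  translation between systems is a bijection on bases; updates return an
  `UpdateMapping` so old coordinates stay resolvable (`resolve_legacy`).
- **Single-path intervals** (`graphcoords.intervals`): start/end
  coordinates plus the ordered region paths traversed; *minimal* and
  *full* text notation, e.g. `(A:1 D F:0)` vs `(A:1 D C F:0)`; parsing of
  both space and comma dialects with SI offset suffixes (`chr14:150m`).
- **Multipath intervals** (`graphcoords.multipath`): critical-subpaths
  and fuzzy-path (central path + edit-distance threshold, global or
  max-local mode) representations, with membership, full expansion and
  set equality.
- **Assembly building** (`graphcoords.assembly`): build *simple*,
  *trimmed* (flanking regions removed from alt loci) and *merged*
  (alignment-based bubble) graphs from placement tables, FASTA and
  alignment segments; exact-match flank detection; a deterministic
  synthetic-fixture generator with full ground truth.
- **Transcripts** (`graphcoords.transcripts`): project BED12/genePred
  annotations onto graph coordinates, categorize alt-locus transcripts
  (A–E/none) against their same-id main-path counterparts, and compare
  transcripts as multipath intervals.

## CLI

```sh
# generate a synthetic dataset with known ground truth
graphcoords make-fixture --out-dir fx --seed 1

# build a graph (simple | trimmed | merged) with both partitionings
graphcoords build-graph --placements fx/placements.tsv --fasta fx/sequences.fa \
    --mode trimmed --out graph.json --gfa graph.gfa

# translate coordinates / intervals between coordinate systems
graphcoords translate --graph graph.json --from hierarchical --to sequential chr1:105
graphcoords translate --graph graph.json --from hierarchical --to sequential \
    "(chr1:30 alt1 chr1:200)"

# interval notation
graphcoords parse-interval  --graph graph.json --partition hierarchical "(A:1 D F:0)"
graphcoords format-interval --graph graph.json --style minimal "(A:1 D C F:0)"

# transcript categories (trimmed graph) and multipath comparison (merged graph)
graphcoords classify-transcripts --graph graph.json --annotations fx/transcripts.bed
graphcoords compare-multipath --graph merged.json --annotations fx/transcripts.bed \
    --mode fuzzy --threshold 2
```

Defaults for any subcommand can be put in a JSON config file
(`graphcoords --config cfg.json <subcommand> ...`); explicit flags win.
Logs go to stderr, results to stdout/files; all error paths exit non-zero
with a single-line reason.

## Conventions

- Offsets are 0-based, intervals half-open `[start, end)`.
- An interval end such as `F:0` is legal: the region path `F` terminates
  the traversal list while contributing zero bases.
- Iteration order is deterministic (sorted by id) everywhere, so outputs
  are reproducible byte-for-byte.
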