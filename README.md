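# sulston

Headless curation of tracked-nuclei cell-lineage data from 4D fluorescence
microscopy.

Automated lineaging pipelines (StarryNite and its relatives) detect and
track fluorescently labelled nuclei frame by frame, producing per-timepoint
record files that encode a forest of cell tracks: each nucleus carries a
predecessor link into the previous frame and up to two successor links into
the next (two successors = a cell division). Curating those results —
validating links, naming cells, editing mistakes — is usually done in a GUI.
`sulston` provides the computational core of that workflow as a library and
command-line tool, for pipelines, batch QC and regression testing:

* **I/O** for the tracker's surfaces: a ZIP-of-CSV nuclei archive, the
  `AuxInfo_v2.xml` metadata file (embryo orientation vectors, voxel
  resolutions), the *C. elegans* Parts List (systematic ↔ functional names)
  and a per-parent expected-division-axis table.
* **Canonical alignment.** Division-direction expectations are stored in the
  canonical embryo frame ("anterior to the left, dorsal up"). Given
  user-supplied image-space AP and LR vectors, the package builds the unique
  proper rotation `R = R_LR · R_AP` (two axis-angle rotations concatenated,
  with explicit handling of the already-canonical and flipped-collinear
  degenerate cases) that maps them onto the canonical axes, and applies it
  to every division axis.
* **Systematic naming.** Daughters are named `parent + suffix` with suffix
  pairs a/p, d/v, l/r chosen from the division direction: a fixed
  founder-division table (P0 → AB/P1, EMS → MS/E, …), then a pluggable
  expected-axis table, then body-axis fallback on the dominant canonical
  axis. Cells can be force-named, and names propagate to descendants.
* **Editing.** A closed set of five commands (ADD, DELETE, LINK, UNLINK,
  SET_POSITION) addressed by (frame, index) coordinates, with per-command
  validation and rollback — and automatic re-naming after every edit.
* **Synthetic embryos.** A deterministic generator emits complete fixture
  bundles (archive + metadata + expected axes + ground-truth names) at any
  rigid orientation, so the whole pipeline is testable without real data.
* **Display mapping.** The linear 16-bit → 8-bit black/white-point mapping
  used to show modern sensor data, plus a percentile-based proposer.

There is no cap on frame or plane counts; archives are read lazily one
frame at a time.

## Worked example

Simulate a two-round embryo in a random 3D orientation, then name it from
its archive and metadata alone:

```sh
sulston simulate --seed 7 --n-rounds 2 --random-orientation --out demo
sulston name demo/nuclei.zip --auxinfo demo/AuxInfo_v2.xml \
        --expected-axes demo/expected_axes.csv \
        --out-csv demo/assignments.csv --out-newick demo/tree.nwk
head -8 demo/assignments.csv
```

```
name,birth,end,parent,provenance
ABa,1,5,,seed
ABp,1,5,,seed
EMS,1,5,,seed
P2,1,5,,seed
ABal,6,10,ABa,expected_axis
ABar,6,10,ABa,expected_axis
ABpl,6,10,ABp,expected_axis
```

The four founders were seeded positionally at the 4-cell stage (`P2` most
posterior, `EMS` most ventral, `ABa` anterior of the remaining pair) after
rotating the embryo back to canonical space from its metadata vectors — here
the AP axis was imaged along `(0.657, 0.511, 0.555)`. Each later row is a
daughter named from its division direction (`provenance` records which rule
fired). The Newick export shows the same forest with branch lengths in
frames × time resolution:

```
((ABald:5,ABalv:5)ABal:5,(ABarl:5,ABarr:5)ABar:5)ABa:5;
```

The bundle's `truth.csv` holds the generator's ground-truth names; on
noise-free data the assignment recovers them exactly, at any orientation.

The same works in Python:

```python
import sulston as s

res = s.generate(s.SimConfig(seed=7, n_rounds=2))
tree = s.build_tracks(res.frames)
transform = s.canonical_transform(res.metadata.ap_vector, res.metadata.lr_vector)
seeds = s.seed_founders(tree, transform, res.metadata)
rules = s.NamingRuleSet(expected_axes=res.expected_axes)
assignments = s.assign_names(tree, transform, rules, res.metadata, seeds=seeds)
```

## Documentation

* `docs/methods.md` — the model, conventions, defaults and limitations.
* `docs/formats.md` — the normative record dialect, edit-script grammar and
  side-car table formats; `docs/auxinfo_v2.xsd` is the metadata schema.
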