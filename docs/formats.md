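# File formats

This file is the normative specification of the formats the package reads
and writes.

## Nuclei archive

A ZIP archive with one text member per frame, named `t%05d.csv` (frame
numbers are 1-based; the reader accepts any member stem ending in a
zero-padded integer and orders members numerically). Frames missing from a
contiguous range are treated as empty, with a warning.

Each line is one nucleus record, comma-separated, RFC-4180 quoting for the
name field, fields in this order:

| # | field | type | notes |
|---|-------|------|-------|
| 1 | time | int ≥ 1 | frame number, matches the member |
| 2 | index | int ≥ 1 | record index within the frame |
| 3 | valid | 1/0 | invalid records carry no links |
| 4 | predecessor | int or −1 | index into the previous frame |
| 5 | successor1 | int or −1 | index into the next frame |
| 6 | successor2 | int or −1 | set only for divisions; implies successor1 |
| 7 | x | real | pixels |
| 8 | y | real | pixels |
| 9 | z | real | planes (fractional allowed) |
| 10 | diameter | real ≥ 0 | pixels |
| 11 | identity | string | cell name, possibly empty; UTF-8 |
| 12 | weight | real ≥ 0 | summed intensity |

Numbers are locale-independent (decimal point, no separators); reals are
written in shortest round-tripping form, so write → read is bit-exact.
Legacy archives with a different column order can be read by supplying a
column map: a whitespace-separated list where entry *k* is the source
column (0-based) holding field *k* of the table above.

## AuxInfo_v2.xml

Root element `auxinfo` (attribute `version="2"`), child elements:

* `ap_vector`, `lr_vector` — three space-separated reals, the image-space
  anterior→posterior and left→right directions (any nonzero length), or
* `orientation` — legacy keyword meaning the embryo is already canonical.

Exactly one of the two styles must be present. Optional children:
`xy_res` (µm/pixel), `z_res` (µm/plane), `time_res` (min/frame),
`bit_depth` (8 or 16), `channels` (≥ 1). Schema: `auxinfo_v2.xsd`.

## Parts List (TSV)

Tab-separated, columns: systematic name, functional name, description.
Later columns optional. Duplicate systematic names are an error;
functional → systematic may be one-to-many.

## Expected-axis table (CSV)

Header `parent_name,ex,ey,ez,suffix_pair`, then one row per parent:
a unit vector in canonical space and a two-character suffix pair (e.g.
`ap`). The daughter on the negative side of the vector takes the first
suffix.

## Ground-truth map (CSV, generator output)

Header `birth_time,first_index,name`: the (frame, index) of a track's
first record and its true systematic name.

## Edit scripts

Line-oriented; blank lines and `#` comments ignored; coordinates are
`time:index` (both 1-based).

```
ADD <t> <x> <y> <z> [diameter]
DELETE <t>:<i>
LINK <t>:<i> <t+1>:<j>
UNLINK <t>:<i> <t+1>:<j>
SET_POSITION <t>:<i> <x> <y> <z>
```
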