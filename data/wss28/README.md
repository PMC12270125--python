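# WSS28 fixture (not transcribed)

This directory is the mount point for the transcribed 28-element western
Scotian Shelf / Bay of Fundy model (27 functional groups + 1 fishing
fleet). The source tables live in the supplementary file of the study
this pipeline reproduces (biomass/pedigree table and the diet matrix),
which is distributed as a DOCX and is **not** bundled here — it could not
be fetched in the build environment, and the main text does not print the
parameter values.

To enable the fixture-dependent acceptance tests and targets, transcribe
the supplementary tables into:

- `groups.csv` — columns
  `name,role,biomass,pb,qb,unassim,catch,pedigree_b,pedigree_pb,pedigree_qb,pedigree_diet`,
  one row per element, `role` ∈ {producer, consumer, detritus, fleet}
  (exactly one fleet row; leave `biomass`/`pb`/`qb` empty where not
  applicable).
- `diet.csv` — square diet-composition matrix over the non-fleet groups,
  prey rows × predator columns, header row and first column carrying the
  group names; consumer columns must sum to 1.

Scenario element names expected by the acceptance tests:
`Phytoplankton`, `Small pelagics`, `Seals`, `Fishery`.

Validate with:

    qnmladder table4 --web data/wss28

which prints the IN/OUT/ALL link-count ladder to compare against the
published table.
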