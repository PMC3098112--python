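# Published decision-tree model for antibody variable-domain
# amyloidogenicity prediction: edge weights, per-germline boost/decrease
# leaves (leaf numbering: 1 = CDR/exposed/increase ... 8 = FR/buried/decrease)
# and per-germline classification thresholds.
#
# provenance "derived" marks weights that follow the ratio-to-max convention
# from the published exclusive-mutation shift counts; "published" marks
# weights taken verbatim from the published table where that convention does
# not reproduce them (the convention-derived value is kept in derived_values).
version: published-v1
weights:
  CDR: 1.0
  FR: 0.79
  CDR-exposed: 0.78
  CDR-buried: 1.0
  FR-exposed: 1.0
  FR-buried: 0.85
  CDR-exposed-increase: 0.69
  CDR-exposed-decrease: 0.31
  CDR-buried-increase: 1.0
  CDR-buried-decrease: 0.76
  FR-exposed-increase: 1.0
  FR-exposed-decrease: 0.95
  FR-buried-increase: 0.74
  FR-buried-decrease: 0.43
provenance:
  CDR: published
  FR: published
  CDR-exposed: derived
  CDR-buried: derived
  FR-exposed: derived
  FR-buried: derived
  CDR-exposed-increase: published
  CDR-exposed-decrease: published
  CDR-buried-increase: derived
  CDR-buried-decrease: derived
  FR-exposed-increase: derived
  FR-exposed-decrease: derived
  FR-buried-increase: published
  FR-buried-decrease: published
derived_values:
  CDR: 0.92
  FR: 1.0
  CDR-exposed-increase: 1.0
  CDR-exposed-decrease: 0.45
  FR-buried-increase: 0.57
  FR-buried-decrease: 1.0
# Boosted (max-separation) and decreased (min-separation) leaves as marked
# in the published per-germline leaf-separation table.  J00248's minimum is
# tied between leaves 4 and 7 (both marked); the lower index is used.
# Z73673's decreased mark (leaf 7) is NOT that column's minimum (leaf 1);
# the printed mark is shipped.
boost:
  J00248: {boosted_leaf: 6, decreased_leaf: 4, factor: 10.0}
  M30446: {boosted_leaf: 4, decreased_leaf: 7, factor: 10.0}
  X72813: {boosted_leaf: 3, decreased_leaf: 4, factor: 10.0}
  X93620: {boosted_leaf: 5, decreased_leaf: 7, factor: 10.0}
  X93627: {boosted_leaf: 8, decreased_leaf: 2, factor: 10.0}
  X93632: {boosted_leaf: 4, decreased_leaf: 3, factor: 10.0}
  X93640: {boosted_leaf: 3, decreased_leaf: 8, factor: 10.0}
  Z22188: {boosted_leaf: 8, decreased_leaf: 4, factor: 10.0}
  Z22191: {boosted_leaf: 2, decreased_leaf: 5, factor: 10.0}
  Z22197: {boosted_leaf: 7, decreased_leaf: 4, factor: 10.0}
  Z22208: {boosted_leaf: 3, decreased_leaf: 7, factor: 10.0}
  Z73673: {boosted_leaf: 2, decreased_leaf: 7, factor: 10.0}
thresholds:
  J00248: 1.70
  M30446: 1.50
  X72813: 1.75
  X93620: 0.65
  X93627: 0.85
  X93632: 1.80
  X93640: 2.50
  Z22188: 0.80
  Z22191: 0.75
  Z22197: 0.65
  Z22208: 1.50
  Z73673: 0.75
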