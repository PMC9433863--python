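# CTCAE v5-style grading bounds for the four cytopenias.
#
# For each analyte, `bounds` lists the lower bounds of grades 1..4 in
# decreasing order, on the analyte's scale.  Grade g applies when the value
# falls in [bounds[g], bounds[g-1]); bounds[0] is the lower limit of normal,
# so grade 0 applies at or above it, and grade 4 extends down to zero.
# A value exactly equal to a bound takes the milder grade (CTCAE phrases
# grades as "< x - y" ranges).
#
# The anemia grade-4 bound is an operational numeric cut (CTCAE defines
# anemia grade 4 clinically as life-threatening, without a number); edit to
# taste.  Lower limits of normal are adult-female reference values.
version: "5.0"
analytes:
  wbc:        # leukopenia, 10^9/L
    toxicity: leukopenia
    unit: "1e9/L"
    bounds: [4.0, 3.0, 2.0, 1.0]
  anc:        # neutropenia, 10^9/L
    toxicity: neutropenia
    unit: "1e9/L"
    bounds: [2.0, 1.5, 1.0, 0.5]
  hgb:        # anemia, g/L
    toxicity: anemia
    unit: "g/L"
    bounds: [120.0, 100.0, 80.0, 65.0]
  plt:        # thrombocytopenia, 10^9/L
    toxicity: thrombocytopenia
    unit: "1e9/L"
    bounds: [150.0, 75.0, 50.0, 25.0]
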