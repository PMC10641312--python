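{
 "genes": [
  "CDKN2A",
  "CCNE1",
  "E2F1",
  "MYBL2",
  "CCND1",
  "CDK6",
  "RB1",
  "PCNA",
  "FOXM1",
  "ESR1",
  "MKI67"
 ],
 "centroid_A": [
  1099.5116277760005,
  429.49672960000015,
  687.1947673600004,
  268.4354560000001,
  40.96000000000001,
  65.53600000000002,
  10.0,
  167.77216000000007,
  104.85760000000002,
  16.0,
  25.6
 ],
 "centroid_H": [
  25.6,
  687.1947673600004,
  1099.5116277760005,
  429.49672960000015,
  65.53600000000002,
  104.85760000000002,
  10.0,
  268.4354560000001,
  167.77216000000007,
  16.0,
  40.96000000000001
 ],
 "centroid_L": [
  16.0,
  25.6,
  10.0,
  40.96000000000001,
  429.49672960000015,
  268.4354560000001,
  1099.5116277760005,
  65.53600000000002,
  104.85760000000002,
  687.1947673600004,
  167.77216000000007
 ],
 "cdkn2a_gene": "CDKN2A",
 "provenance": "synthetic placeholder reference (generated, not derived from tumors)"
}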