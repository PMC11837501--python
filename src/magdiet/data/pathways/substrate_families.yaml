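# Substrate-class -> gene-family lists used for copy totals (the axes of the
# completeness-normalized substrate profile). Hemicellulose is the union of
# the xylan, mannan and xyloglucan chains, each family counted once. Protein
# lists MEROPS exopeptidase families (amino-, carboxy- and dipeptidases);
# starch lists amylase families. Edit to match your annotation scheme.
substrate_families:
  cellulose:
    [CAZY:GH5, CAZY:GH8, CAZY:GH9, CAZY:GH45, CAZY:GH6, CAZY:GH48, CAZY:GH1, CAZY:GH3]
  hemicellulose:
    [CAZY:GH10, CAZY:GH11, CAZY:GH43, CAZY:GH39, CAZY:GH52,
     CAZY:GH26, CAZY:GH113, CAZY:GH2, CAZY:GH130,
     CAZY:GH74, CAZY:GH16, CAZY:GH31, CAZY:GH1, CAZY:GH3]
  chitin:
    [CAZY:GH18, CAZY:GH19, CAZY:GH20, CAZY:CE4, CAZY:GH46, CAZY:GH75, CAZY:GH2]
  starch:
    [CAZY:GH13, CAZY:GH14, CAZY:GH15, CAZY:GH57, CAZY:GH97, CAZY:GH77]
  protein:
    [MEROPS:M01, MEROPS:M17, MEROPS:M24, MEROPS:M28, MEROPS:M42,
     MEROPS:M20, MEROPS:M14, MEROPS:S10, MEROPS:S33, MEROPS:C69]
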