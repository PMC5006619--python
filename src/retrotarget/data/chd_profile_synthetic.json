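{
 "description": "Synthetic chromo-domain profile alignment (constructed fixture, not derived from any published alignment). Cage columns are the three aromatic-cage positions.",
 "cage_columns": [
  18,
  22,
  25
 ],
 "rows": [
  "EYVVEKILDHRVRKGKVEYYLKWKGYSDEDNTWEPEENLDCPDLIAEFEQSRKD",
  "EYHVWGILQHDVHKGKVGYYLKWKGYSKEDNCWEPIVQLDCPDLIAEFCQSRKD",
  "EYVVMHILDARVRKGTVEYYLKWKGYEHEDNTWEPEENLDCPDLIAEYEKSLKD",
  "EYVVEKILDHRVRKGKVEYYLKWKGYSDEDNTWEPEEHLDCPDGICEFEQSTKD",
  "EYVPEKILDHRVRNGKFEYYLKWKGYSDEGNIWEPDENPDCPHLFAEFEQSRKD",
  "EYVQEKNLDHRVRKGNVEYYLKWKGYSDIDNTQEPEENLDCPDLFLEFEQIRKD",
  "EYVVEKIVDHRVDKGKVEYYLHWKGYSDEINTWEPEENLDCPICIAEMEQSRKD",
  "EPVVEKNLDHQVRKGKVEYYLKWKGYSDEDNSWEPEVNLYCPKLILEFEGSRKL"
 ]
}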