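{
 "fig3_folds.tsv": "168db96fd162a71da100531b3368d4e25c276659bb810e0741140c7ad2175ec2",
 "kd_tm.tsv": "4564d77a6142dc8d88e784cbeeff155ef602081e82d659022220f9d832a642b3",
 "table1_sites.tsv": "8106c58b4d5f0a5ffe58f0bf68a3c488f3b67841f073e57e85bdf86999cbafab",
 "table2_consensus_z.tsv": "bf4a0e9f440c5122343ecff23254357fec9eabf674b1c275fe7969911014aee9"
}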