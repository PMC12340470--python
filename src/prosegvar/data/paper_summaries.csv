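study,comparison,metric,center_kind,center,sd,iqr_low,iqr_high,n,note
present,manual_vs_semiauto,asd,median,1.43,,1.20,1.90,315,
present,inter_manual_softssm,asd,median,1.5,,1.2,1.8,132,
present,inter_manual_ssm,asd,median,2.6,,2.3,3.0,132,
present,inter_semiauto,asd,median,1.4,,1.1,1.9,343,
present,intra_manual_ssm,asd,median,2.2,,1.9,2.5,18,abstract prints IQR 1.9-2.6; results section and table print 1.9-2.5
present,intra_manual_softssm,asd,median,1.0,,0.8,1.1,18,
present,intra_semiauto,asd,median,1.2,,0.9,1.7,19,
present,manual_vs_consensus,asd,median,1.38,,1.09,1.78,125,
tutar,manual_vs_semiauto,mad,mean,1.26,0.41,,,30,
gong,manual_vs_semiauto,mad,mean,1.36,0.58,,,16,
shen,manual_vs_semiauto,asd,mean,3.20,0.87,,,10,
pathak,manual_vs_semiauto,asd,mean,4.0,1.5,,,16,
tutar,inter_manual,mad,mean,1.34,0.66,,,30,
gong,inter_manual,mad,mean,1.82,1.44,,,16,
pathak,inter_manual,asd,mean,1.8,1.4,,,16,
pathak,inter_semiauto,asd,mean,0.7,0.4,,,16,
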