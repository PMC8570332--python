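morphology,virus,structure,twist_deg,rise_ang,resolution_ang,emdb_id,host_gram,citation
myophage,phage G,non-contracted sheath,20.57,41.53,7-8,EMD-25155,+,current study
myophage,phage G,contracted sheath,27.18,18.89,6-7,EMD-25154,+,current study
myophage,phi812K1-420,non-contracted sheath,21.4,38.9,6.2,EMD-4051,-,ref11
myophage,phi812K1-420,contracted sheath,30.7,18.8,4.2,EMD-4052,-,ref11
myophage,phiRSL1,non-contracted sheath,22.1,37.9,9.6,EMD-2244,-,ref10
myophage,phiKZ,contracted poly sheath,34.1,17.9,19.0,EMD-5331,-,ref33
myophage,phiKZ,non-contracted sheath,22,36.7,18.0,EMD-5332,-,ref33
myophage,T4,contracted sheath,32.9,16.4,,,-,ref44;ref45
myophage,T4,non-contracted,17.2,40.6,,,-,ref44;ref45
myophage,T4,tube,18.2,40.2,3.4,EMD-8767,-,ref45
siphophage,SPP1,tube,38.5,21.9,4.0,EMD-10792,+,ref35
siphophage,YSD1,tail,19.7,41.2,3.5,EMD-22183,-,ref38
siphophage,lambda,tail,17.5,42.8,6.4,EMD-20242,-,ref46
siphophage,T5,tail,39.1,40.6,6.0,EMD-3692,-,ref39
siphophage,p2,tail,46.3,37.4,22.0,EMD-2464,-,ref42
siphophage,Araucaria,tail,26,38,24.0,EMD-2337,+,ref36
siphophage,TP901-1,tail,38,22.4,20.0,EMD-2228,+,ref47
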