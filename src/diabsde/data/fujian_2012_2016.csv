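year,lambda,theta,incidence,nu_delta,mu
2012,0.0211,0.0089,0.0573,0.00526,0.00191
2013,0.0401,0.0101,0.1010,0.00611,0.00081
2014,0.0612,0.0293,0.1536,0.00650,0.00118
2015,0.0812,0.0387,0.2006,0.00706,0.00157
2016,0.0991,0.0591,0.2436,0.00664,0.00198
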