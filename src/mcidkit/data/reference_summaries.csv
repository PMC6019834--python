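instrument,scheme,period,n,mean,sd,icc
CAT,grc15,T1,196,-3.1,5.3,0.7
CAT,grc15,T2,107,-2.7,6.4,0.6
CAT,grc15,T3,96,-2.7,6.7,0.5
CAT,grc15,T4,80,-2.3,6.1,0.6
CAT,grc15,T5,88,-2.8,6.7,0.5
CAT,grc5,T5,81,-1.4,5.9,0.6
CCQ,grc15,T1,196,-0.6,0.8,0.7
CCQ,grc15,T2,107,-0.4,1.0,0.6
CCQ,grc15,T3,96,-0.4,1.1,0.5
CCQ,grc15,T4,80,-0.5,0.8,0.7
CCQ,grc15,T5,88,-0.5,1.0,0.5
CCQ,grc5,T5,81,-0.3,0.8,0.6
SGRQ,grc15,T1,196,-8.4,11.8,0.7
SGRQ,grc15,T2,107,-7.6,13.8,0.7
SGRQ,grc15,T3,96,-9.2,14.0,0.7
SGRQ,grc15,T4,80,-10.3,12.9,0.7
SGRQ,grc15,T5,88,-8.8,14.1,0.6
SGRQ,grc5,T5,81,-7.7,12.9,0.6
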