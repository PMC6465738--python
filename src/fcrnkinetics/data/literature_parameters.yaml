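# Literature-sourced parameter values for the four-compartment model of
# FcRn-mediated IgG recycling.  Rate constants day^-1, kon l umol^-1 day^-1,
# Rtot umol, volumes litres.  The peripheral volume v2 has no sourced value
# and is never needed by the dynamics, so it is omitted.
k21: 0.51
k31: 0.18
k12: 0.41
k14: 5.0
k03: 3.0
kon: 1000.0
koff: 100.0
Rtot: 14.0
v1: 2.9
v3: 0.34
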