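((((msp0001:0.46181022107564157,(msp0002:0.363174294377029,(msp0003:0.1542907977168358,msp0004:0.1542907977168358):0.2088834966601932):0.09863592669861258):0.025901164359944016,(msp0005:0.06001045480035683,msp0006:0.06001045480035683):0.4277009306352288):0.06228861456441443,(msp0007:0.37432170630069045,(msp0008:0.3564773346779423,((msp0009:0.10622344506252747,msp0010:0.10622344506252747):0.10927126461662344,(msp0011:0.06457705411972013,msp0012:0.06457705411972013):0.1509176555594308):0.14098262499879144):0.017844371622748045):0.17567829369930968):0.45,((ssp0001:0.33839785067703265,(ssp0002:0.29927667291909277,(ssp0003:0.2183235661384009,ssp0004:0.2183235661384009):0.08095310678069188):0.039121177757939885):0.4116021493229674,((ssp0005:0.31184258785149355,ssp0006:0.31184258785149355):0.04905567081623803,(ssp0007:0.1757323750534653,ssp0008:0.1757323750534653):0.18516588361426625):0.3891017413322684):0.25);
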