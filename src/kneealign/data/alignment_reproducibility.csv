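case,operator,run,variable,value
1,A,1,femoral_fe,1.1
1,A,1,femoral_vv,-0.6
1,A,1,femoral_ie,-0.8
1,A,1,tibial_fe,7.1
1,A,1,tibial_vv,0.6
1,A,1,tibial_ie,5.9
1,A,2,femoral_fe,1.0
1,A,2,femoral_vv,-0.5
1,A,2,femoral_ie,-1.2
1,A,2,tibial_fe,7.0
1,A,2,tibial_vv,0.4
1,A,2,tibial_ie,6.2
1,B,1,femoral_fe,1.0
1,B,1,femoral_vv,-0.8
1,B,1,femoral_ie,-1.5
1,B,1,tibial_fe,7.0
1,B,1,tibial_vv,0.5
1,B,1,tibial_ie,4.5
1,B,2,femoral_fe,0.8
1,B,2,femoral_vv,-0.7
1,B,2,femoral_ie,-0.8
1,B,2,tibial_fe,7.4
1,B,2,tibial_vv,0.4
1,B,2,tibial_ie,4.7
1,C,1,femoral_fe,1.1
1,C,1,femoral_vv,-0.6
1,C,1,femoral_ie,-1.8
1,C,1,tibial_fe,6.9
1,C,1,tibial_vv,0.8
1,C,1,tibial_ie,5.5
1,C,2,femoral_fe,1.1
1,C,2,femoral_vv,-0.4
1,C,2,femoral_ie,-1.0
1,C,2,tibial_fe,7.2
1,C,2,tibial_vv,0.6
1,C,2,tibial_ie,5.9
2,A,1,femoral_fe,1.9
2,A,1,femoral_vv,-0.9
2,A,1,femoral_ie,0.1
2,A,1,tibial_fe,8.2
2,A,1,tibial_vv,1.5
2,A,1,tibial_ie,3.0
2,A,2,femoral_fe,2.3
2,A,2,femoral_vv,-0.8
2,A,2,femoral_ie,-0.1
2,A,2,tibial_fe,7.7
2,A,2,tibial_vv,1.8
2,A,2,tibial_ie,2.7
2,B,1,femoral_fe,2.3
2,B,1,femoral_vv,-0.7
2,B,1,femoral_ie,-0.2
2,B,1,tibial_fe,7.9
2,B,1,tibial_vv,1.7
2,B,1,tibial_ie,1.7
2,B,2,femoral_fe,2.1
2,B,2,femoral_vv,-0.8
2,B,2,femoral_ie,0.4
2,B,2,tibial_fe,8.4
2,B,2,tibial_vv,1.4
2,B,2,tibial_ie,2.8
2,C,1,femoral_fe,2.0
2,C,1,femoral_vv,-0.7
2,C,1,femoral_ie,-0.2
2,C,1,tibial_fe,7.9
2,C,1,tibial_vv,1.0
2,C,1,tibial_ie,2.3
2,C,2,femoral_fe,1.8
2,C,2,femoral_vv,-0.8
2,C,2,femoral_ie,0.0
2,C,2,tibial_fe,8.4
2,C,2,tibial_vv,1.5
2,C,2,tibial_ie,2.8
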