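case,operator,run,variable,value
1,A,1,lat_condyle,6.5
1,A,1,med_condyle,6.0
1,A,1,post_lat_condyle,10.0
1,A,1,post_med_condyle,10.3
1,A,1,lat_plateau,11.2
1,A,1,med_plateau,10.0
1,A,2,lat_condyle,6.2
1,A,2,med_condyle,5.7
1,A,2,post_lat_condyle,10.0
1,A,2,post_med_condyle,10.7
1,A,2,lat_plateau,10.3
1,A,2,med_plateau,9.0
1,B,1,lat_condyle,6.1
1,B,1,med_condyle,5.4
1,B,1,post_lat_condyle,10.2
1,B,1,post_med_condyle,11.1
1,B,1,lat_plateau,10.5
1,B,1,med_plateau,9.3
1,B,2,lat_condyle,6.8
1,B,2,med_condyle,6.1
1,B,2,post_lat_condyle,10.2
1,B,2,post_med_condyle,10.6
1,B,2,lat_plateau,11.1
1,B,2,med_plateau,9.8
1,C,1,lat_condyle,6.2
1,C,1,med_condyle,5.7
1,C,1,post_lat_condyle,9.5
1,C,1,post_med_condyle,10.7
1,C,1,lat_plateau,10.7
1,C,1,med_plateau,9.6
1,C,2,lat_condyle,6.4
1,C,2,med_condyle,6.0
1,C,2,post_lat_condyle,9.9
1,C,2,post_med_condyle,10.3
1,C,2,lat_plateau,11.1
1,C,2,med_plateau,9.9
2,A,1,lat_condyle,6.0
2,A,1,med_condyle,7.4
2,A,1,post_lat_condyle,10.9
2,A,1,post_med_condyle,10.3
2,A,1,lat_plateau,11.0
2,A,1,med_plateau,6.7
2,A,2,lat_condyle,6.2
2,A,2,med_condyle,7.8
2,A,2,post_lat_condyle,10.8
2,A,2,post_med_condyle,10.3
2,A,2,lat_plateau,11.1
2,A,2,med_plateau,7.0
2,B,1,lat_condyle,6.1
2,B,1,med_condyle,7.7
2,B,1,post_lat_condyle,10.6
2,B,1,post_med_condyle,10.2
2,B,1,lat_plateau,10.9
2,B,1,med_plateau,6.7
2,B,2,lat_condyle,6.1
2,B,2,med_condyle,7.6
2,B,2,post_lat_condyle,10.8
2,B,2,post_med_condyle,9.9
2,B,2,lat_plateau,11.2
2,B,2,med_plateau,6.9
2,C,1,lat_condyle,5.9
2,C,1,med_condyle,7.5
2,C,1,post_lat_condyle,11.0
2,C,1,post_med_condyle,10.6
2,C,1,lat_plateau,11.0
2,C,1,med_plateau,6.3
2,C,2,lat_condyle,6.0
2,C,2,med_condyle,7.4
2,C,2,post_lat_condyle,10.9
2,C,2,post_med_condyle,10.4
2,C,2,lat_plateau,10.9
2,C,2,med_plateau,6.6
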