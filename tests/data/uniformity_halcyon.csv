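accelerator,algorithm,mode,gap,series,center,left,top,right,bottom,d_left,d_top,d_right,d_bottom,mean4,series_mean
Halcyon,CBCT,Pelvis,i_0,s_1,7.52,1.29,1.16,-1.06,-1.73,-6.22,-6.35,-8.57,-9.25,-7.60,-7.41
Halcyon,CBCT,Pelvis,i_0,s_2,7.37,0.22,1.05,0.69,-1.33,-7.15,-6.32,-6.68,-8.70,-7.21,
Halcyon,CBCT,Pelvis,i_5,s_1,7.37,0.22,1.05,0.69,-1.33,-7.15,-6.32,-6.68,-8.70,-7.21,-8.04
Halcyon,CBCT,Pelvis,i_5,s_2,8.02,1.17,1.42,-1.23,-1.39,-6.85,-6.60,-9.26,-9.42,-8.03,
Halcyon,CBCT,Pelvis,i_5,s_3,8.74,-0.09,0.55,0.58,-1.25,-8.83,-8.19,-8.16,-9.99,-8.79,
Halcyon,CBCT,Pelvis,i_5,s_4,7.88,1.50,0.60,-1.48,-1.45,-6.38,-7.29,-9.36,-9.33,-8.09,
Halcyon,CBCT,Pelvis,i_5,s_5,7.95,0.05,1.00,0.27,-1.72,-7.90,-6.95,-7.69,-9.68,-8.06,
Halcyon,CBCT,PelvisLarge,i_0,s_1,7.99,4.37,5.56,4.54,2.51,-3.62,-2.42,-3.45,-5.47,-3.74,-4.17
Halcyon,CBCT,PelvisLarge,i_0,s_2,8.84,3.52,5.02,5.64,2.76,-5.32,-3.82,-3.20,-6.07,-4.60,
Halcyon,CBCT,PelvisLarge,i_5,s_1,10.20,2.51,2.73,0.46,-0.59,-7.69,-7.48,-9.75,-10.80,-8.93,-8.77
Halcyon,CBCT,PelvisLarge,i_5,s_2,9.86,1.29,2.44,1.65,-0.65,-8.58,-7.42,-8.21,-10.52,-8.68,
Halcyon,CBCT,PelvisLarge,i_5,s_3,9.79,2.44,2.46,0.36,-0.73,-7.35,-7.33,-9.43,-10.52,-8.66,
Halcyon,CBCT,PelvisLarge,i_5,s_4,9.92,1.33,2.31,1.75,-0.79,-8.59,-7.61,-8.17,-10.71,-8.77,
Halcyon,CBCT,PelvisLarge,i_5,s_5,9.74,2.27,2.15,0.20,-0.83,-7.48,-7.59,-9.55,-10.58,-8.80,
Halcyon,iCBCT,Pelvis,i_0,s_1,2.76,-8.60,-9.12,-10.29,-10.05,-11.36,-11.87,-13.04,-12.81,-12.27,-12.43
Halcyon,iCBCT,Pelvis,i_0,s_2,3.23,-8.32,-8.85,-10.04,-10.23,-11.55,-12.08,-13.27,-13.47,-12.59,
Halcyon,iCBCT,Pelvis,i_5,s_1,4.25,-8.04,-7.77,-8.50,-9.48,-12.29,-12.03,-12.75,-13.73,-12.70,-12.42
Halcyon,iCBCT,Pelvis,i_5,s_2,3.57,-7.29,-7.72,-9.59,-9.37,-10.86,-11.29,-13.16,-12.93,-12.06,
Halcyon,iCBCT,Pelvis,i_5,s_3,3.62,-7.83,-7.43,-8.88,-9.46,-11.46,-11.05,-12.50,-13.08,-12.02,
Halcyon,iCBCT,Pelvis,i_5,s_4,4.06,-7.52,-7.94,-9.20,-9.16,-11.57,-11.99,-13.26,-13.21,-12.51,
Halcyon,iCBCT,Pelvis,i_5,s_5,4.02,-8.41,-7.91,-9.14,-9.64,-12.42,-11.93,-13.16,-13.66,-12.79,
Halcyon,iCBCT,PelvisLarge,i_0,s_1,3.71,-3.45,-3.29,-3.90,-5.02,-7.16,-7.00,-7.61,-8.73,-7.62,-8.07
Halcyon,iCBCT,PelvisLarge,i_0,s_2,4.69,-3.61,-3.27,-3.56,-4.88,-8.30,-7.96,-8.25,-9.57,-8.52,
Halcyon,iCBCT,PelvisLarge,i_5,s_1,5.45,-4.03,-4.36,-5.48,-6.27,-9.49,-9.82,-10.94,-11.72,-10.49,-11.63
Halcyon,iCBCT,PelvisLarge,i_5,s_2,5.87,-4.92,-4.74,-5.35,-6.80,-10.79,-10.61,-11.22,-12.66,-11.32,
Halcyon,iCBCT,PelvisLarge,i_5,s_3,6.39,-4.76,-4.45,-6.03,-6.54,-11.14,-10.84,-12.41,-12.92,-11.83,
Halcyon,iCBCT,PelvisLarge,i_5,s_4,6.23,-5.42,-4.99,-5.97,-7.10,-11.65,-11.22,-12.20,-13.33,-12.10,
Halcyon,iCBCT,PelvisLarge,i_5,s_5,6.33,-4.94,-4.75,-6.91,-7.66,-11.27,-11.08,-13.24,-13.98,-12.39,
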