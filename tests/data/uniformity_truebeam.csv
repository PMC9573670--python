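accelerator,algorithm,mode,gap,series,center,left,top,right,bottom,d_left,d_top,d_right,d_bottom,mean4,series_mean
TrueBeam,CBCT,Pelvis,i_0,s_1,11.58,1.89,3.86,6.36,2.70,-9.69,-7.73,-5.23,-8.88,-7.88,-7.86
TrueBeam,CBCT,Pelvis,i_0,s_2,10.61,3.82,4.11,2.93,1.83,-6.79,-6.50,-7.68,-8.78,-7.44,
TrueBeam,CBCT,Pelvis,i_0,s_3,11.43,2.33,3.89,5.57,2.80,-9.10,-7.53,-5.85,-8.62,-7.78,
TrueBeam,CBCT,Pelvis,i_0,s_4,11.22,3.45,3.93,3.00,1.59,-7.76,-7.29,-8.21,-9.63,-8.22,
TrueBeam,CBCT,Pelvis,i_0,s_5,11.49,2.20,3.46,5.48,2.83,-9.29,-8.03,-6.01,-8.66,-8.00,
TrueBeam,CBCT,Pelvis,i_5,s_1,13.42,3.28,5.41,7.57,4.01,-10.13,-8.01,-5.84,-9.40,-8.35,-8.02
TrueBeam,CBCT,Pelvis,i_5,s_2,12.21,5.29,5.20,3.71,2.88,-6.92,-7.01,-8.50,-9.33,-7.94,
TrueBeam,CBCT,Pelvis,i_5,s_3,12.89,3.03,4.92,7.38,3.82,-9.87,-7.97,-5.51,-9.08,-8.11,
TrueBeam,CBCT,Pelvis,i_5,s_4,11.72,4.97,5.24,3.41,2.63,-6.75,-6.49,-8.32,-9.10,-7.66,
TrueBeam,CBCT,Pelvis,i_5,s_5,12.51,2.41,4.96,6.91,3.55,-10.10,-7.55,-5.60,-8.96,-8.05,
TrueBeam,CBCT,PelvisLarge,i_0,s_1,28.42,7.87,7.16,5.87,5.30,-20.55,-21.27,-22.55,-23.12,-21.87,-22.33
TrueBeam,CBCT,PelvisLarge,i_0,s_2,30.88,6.77,9.49,11.44,7.46,-24.10,-21.39,-19.44,-23.42,-22.09,
TrueBeam,CBCT,PelvisLarge,i_0,s_3,29.77,8.08,8.20,6.94,6.13,-21.69,-21.57,-22.82,-23.64,-22.43,
TrueBeam,CBCT,PelvisLarge,i_0,s_4,30.74,6.86,8.67,10.31,6.59,-23.88,-22.07,-20.43,-24.15,-22.63,
TrueBeam,CBCT,PelvisLarge,i_0,s_5,28.87,7.09,6.92,6.00,4.96,-21.77,-21.95,-22.87,-23.91,-22.62,
TrueBeam,CBCT,PelvisLarge,i_5,s_1,27.00,3.20,5.31,7.50,3.57,-23.80,-21.69,-19.50,-23.43,-22.10,-22.10
TrueBeam,CBCT,PelvisLarge,i_5,s_2,25.58,3.76,3.99,2.51,1.86,-21.82,-21.59,-23.07,-23.71,-22.55,
TrueBeam,CBCT,PelvisLarge,i_5,s_3,26.25,2.47,4.66,6.23,2.79,-23.78,-21.59,-20.02,-23.46,-22.21,
TrueBeam,CBCT,PelvisLarge,i_5,s_4,24.32,3.39,3.11,2.04,0.99,-20.93,-21.22,-22.29,-23.33,-21.94,
TrueBeam,CBCT,PelvisLarge,i_5,s_5,24.89,1.73,3.83,5.19,2.00,-23.17,-21.06,-19.70,-22.89,-21.70,
TrueBeam,iCBCT,Pelvis,i_0,s_1,-6.73,-9.97,-9.19,-11.17,-11.32,-3.24,-2.46,-4.44,-4.59,-3.68,-4.12
TrueBeam,iCBCT,Pelvis,i_0,s_2,-5.97,-11.10,-9.39,-9.65,-10.72,-5.13,-3.43,-3.68,-4.75,-4.25,
TrueBeam,iCBCT,Pelvis,i_0,s_3,-7.00,-11.00,-10.26,-11.84,-12.18,-4.00,-3.26,-4.84,-5.18,-4.32,
TrueBeam,iCBCT,Pelvis,i_0,s_4,-6.76,-11.64,-10.16,-10.48,-11.31,-4.88,-3.41,-3.73,-4.56,-4.14,
TrueBeam,iCBCT,Pelvis,i_0,s_5,-7.61,-11.31,-10.72,-12.56,-12.61,-3.70,-3.11,-4.95,-5.00,-4.19,
TrueBeam,iCBCT,Pelvis,i_5,s_1,-5.27,-8.69,-8.06,-10.00,-10.24,-3.42,-2.79,-4.73,-4.97,-3.98,-4.11
TrueBeam,iCBCT,Pelvis,i_5,s_2,-4.11,-9.91,-8.03,-7.71,-9.00,-5.80,-3.92,-3.60,-4.89,-4.55,
TrueBeam,iCBCT,Pelvis,i_5,s_3,-4.88,-8.45,-7.76,-9.85,-10.10,-3.58,-2.88,-4.97,-5.22,-4.16,
TrueBeam,iCBCT,Pelvis,i_5,s_4,-4.89,-10.24,-8.20,-7.86,-9.52,-5.36,-3.31,-2.97,-4.63,-4.07,
TrueBeam,iCBCT,Pelvis,i_5,s_5,-5.85,-8.98,-8.57,-10.20,-10.69,-3.13,-2.72,-4.36,-4.84,-3.76,
TrueBeam,iCBCT,PelvisLarge,i_0,s_1,-0.71,-0.39,-0.27,-2.44,-2.68,0.32,0.45,-1.72,-1.96,-0.73,-2.68
TrueBeam,iCBCT,PelvisLarge,i_0,s_2,0.36,-0.88,0.13,-1.43,-2.25,-1.24,-0.24,-1.79,-2.62,-1.47,
TrueBeam,iCBCT,PelvisLarge,i_0,s_3,-2.03,-2.82,-2.33,-4.19,-4.92,-0.78,-0.29,-2.15,-2.89,-1.53,
TrueBeam,iCBCT,PelvisLarge,i_0,s_4,-0.62,-2.27,-1.37,-3.29,-4.17,-1.65,-0.75,-2.67,-3.54,-2.15,
TrueBeam,iCBCT,PelvisLarge,i_0,s_5,17.41,10.01,11.51,10.38,7.62,-7.39,-5.90,-7.03,-9.79,-7.53,
TrueBeam,iCBCT,PelvisLarge,i_5,s_1,-2.01,-3.96,-2.27,-3.91,-5.36,-1.95,-0.26,-1.90,-3.35,-1.87,-2.12
TrueBeam,iCBCT,PelvisLarge,i_5,s_2,-3.98,-4.73,-4.87,-6.89,-7.21,-0.75,-0.89,-2.91,-3.24,-1.95,
TrueBeam,iCBCT,PelvisLarge,i_5,s_3,-2.49,-5.10,-3.40,-5.02,-6.42,-2.62,-0.91,-2.53,-3.93,-2.50,
TrueBeam,iCBCT,PelvisLarge,i_5,s_4,-4.69,-5.94,-5.69,-7.66,-8.24,-1.25,-1.00,-2.97,-3.55,-2.19,
TrueBeam,iCBCT,PelvisLarge,i_5,s_5,-3.36,-5.42,-3.78,-5.80,-6.79,-2.07,-0.42,-2.44,-3.44,-2.09,
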