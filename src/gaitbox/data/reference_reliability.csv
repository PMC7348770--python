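config,variable,side,category,test_mean,test_sd,retest_mean,retest_sd,dif_mean,dif_sd,icc,mdces95,mdc95
imu,Step length [cm],R,step,58.8,4.6,58.7,4.8,-0.1,2.4,0.93,0.8,3.5
imu,Step length [cm],L,step,58.0,5.0,58.6,5.0,0.7,2.1,0.95,0.6,3.0
imu,Step width [cm],R,step,8.9,3.5,8.1,4.0,-0.8,3.5,0.72,1.6,5.5
imu,Step width [cm],L,step,10.1,4.4,9.9,3.6,-0.1,4.1,0.64,1.5,6.6
imu,Single support [%],R,support,35.2,2.3,35.6,2.2,0.4,1.1,0.93,0.7,1.6
imu,Single support [%],L,support,36.0,2.1,36.4,2.6,0.4,1.3,0.91,0.9,1.9
imu,Double support [%],R,support,29.0,3.9,28.2,4.2,-0.8,1.9,0.94,0.7,2.7
imu,Double support [%],L,support,29.0,4.0,28.1,4.4,-0.8,2.0,0.94,0.7,2.8
imu,Gait speed [cm/s],both,speed,121.8,12.4,123.3,12.9,0.1,0.2,0.97,0.5,6.5
imu,Range of trunk tilt T2 to T5 [deg],R,kinematic,10.0,2.4,9.8,2.8,-0.2,1.2,0.94,0.7,1.7
imu,Range of trunk tilt T2 to T5 [deg],L,kinematic,10.0,2.4,9.8,2.7,-0.2,1.2,0.94,0.7,1.7
imu,Range of pelvic tilt T1 to T4 [deg],R,kinematic,4.8,2.6,4.6,2.3,-0.2,1.1,0.95,0.6,1.5
imu,Range of pelvic tilt T1 to T4 [deg],L,kinematic,4.7,2.5,4.5,2.3,-0.2,1.1,0.95,0.6,1.5
imu,Range of hip flexion-extension T1 to T4 [deg],R,kinematic,35.0,3.5,35.3,4.0,0.4,1.9,0.93,0.8,2.8
imu,Range of hip flexion-extension T1 to T4 [deg],L,kinematic,35.3,4.0,35.6,3.8,0.3,2.5,0.89,0.9,3.6
imu,Range of hip adduction-abduction T4 to T5 [deg],R,kinematic,7.7,2.3,7.7,2.4,0.0,1.8,0.83,1.2,2.7
imu,Range of hip adduction-abduction T4 to T5 [deg],L,kinematic,8.6,2.4,8.9,2.8,0.3,1.9,0.85,1.2,2.8
imu,Range of knee flexion-extension T4 to T5 [deg],R,kinematic,34.9,6.2,34.2,7.1,-0.8,3.0,0.95,0.7,4.2
imu,Range of knee flexion-extension T4 to T5 [deg],L,kinematic,37.3,6.4,36.2,6.5,-1.0,2.6,0.96,0.6,3.7
imu,Range of ankle dorsi-plantar flexion T4 to T5 [deg],R,kinematic,23.2,4.0,22.6,4.0,-0.6,2.1,0.92,0.8,3.1
imu,Range of ankle dorsi-plantar flexion T4 to T5 [deg],L,kinematic,22.6,3.5,23.2,3.3,0.5,2.1,0.89,0.9,3.1
imu,Range of ankle inversion-eversion T1 to T3 [deg],R,kinematic,8.1,4.2,9.5,5.2,1.4,3.3,0.86,1.1,4.8
imu,Range of ankle inversion-eversion T1 to T3 [deg],L,kinematic,8.5,3.9,9.2,4.3,0.7,3.0,0.84,1.2,4.5
optical,Step length [cm],R,step,59.5,4.2,59.5,3.9,0.0,1.6,0.96,0.5,2.3
optical,Step length [cm],L,step,58.2,4.0,58.4,4.3,0.2,1.4,0.97,0.5,2.0
optical,Step width [cm],R,step,12.8,2.3,12.6,2.6,-0.3,1.2,0.94,0.7,1.7
optical,Step width [cm],L,step,12.0,2.1,11.8,2.5,-0.2,1.1,0.94,0.8,1.6
optical,Single support [%],R,support,39.9,0.9,39.8,0.9,0.0,0.5,0.89,0.9,0.8
optical,Single support [%],L,support,39.8,0.8,39.7,0.7,0.0,0.3,0.95,0.6,0.5
optical,Double support [%],R,support,20.4,1.5,20.4,1.5,0.1,0.7,0.95,0.6,1.0
optical,Double support [%],L,support,20.4,1.5,20.4,1.5,0.0,0.7,0.95,0.6,0.9
optical,Gait speed [cm/s],both,speed,114.2,3.7,114.3,3.8,0.0,0.0,1.00,0.2,0.7
optical,Range of trunk tilt T2 to T5 [deg],R,kinematic,3.3,2.1,3.5,1.9,0.2,1.4,0.87,1.0,2.0
optical,Range of trunk tilt T2 to T5 [deg],L,kinematic,3.3,2.1,3.5,1.9,0.2,1.3,0.88,0.9,1.9
optical,Range of pelvic tilt T1 to T4 [deg],R,kinematic,5.2,2.1,5.1,2.0,-0.1,1.0,0.94,0.7,1.4
optical,Range of pelvic tilt T1 to T4 [deg],L,kinematic,5.2,2.1,5.1,2.0,-0.1,1.0,0.94,0.7,1.4
optical,Range of hip flexion-extension T1 to T4 [deg],R,kinematic,32.9,3.3,33.2,3.6,0.3,1.6,0.95,0.7,2.3
optical,Range of hip flexion-extension T1 to T4 [deg],L,kinematic,33.4,3.6,33.1,3.6,-0.3,1.8,0.93,0.7,2.6
optical,Range of hip adduction-abduction T4 to T5 [deg],R,kinematic,5.1,1.0,5.2,1.1,0.2,0.5,0.93,0.8,0.8
optical,Range of hip adduction-abduction T4 to T5 [deg],L,kinematic,4.9,1.0,4.9,1.1,0.0,0.6,0.92,0.8,0.8
optical,Range of knee flexion-extension T4 to T5 [deg],R,kinematic,22.4,2.6,22.9,2.6,0.5,1.2,0.94,0.7,1.7
optical,Range of knee flexion-extension T4 to T5 [deg],L,kinematic,22.0,2.6,22.2,3.1,0.1,1.6,0.91,0.9,2.4
optical,Range of ankle dorsi-plantar flexion T4 to T5 [deg],R,kinematic,15.6,1.6,15.4,2.0,-0.2,1.6,0.77,1.5,2.4
optical,Range of ankle dorsi-plantar flexion T4 to T5 [deg],L,kinematic,14.9,1.6,15.1,1.9,0.2,1.2,0.87,1.1,1.7
optical,Range of ankle inversion-eversion T1 to T3 [deg],R,kinematic,9.1,3.7,9.3,3.9,0.2,1.6,0.95,0.6,2.3
optical,Range of ankle inversion-eversion T1 to T3 [deg],L,kinematic,8.8,3.8,8.8,4.2,0.0,1.3,0.97,0.5,1.8
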