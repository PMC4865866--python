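# energy_meV,model_counts (elastic A=1000, bg=5, DHO Omega=3 Gamma=1 I=100, T=318 K, RF fwhm=1.7 eta=0.5; independent quadrature reference)
-1.500000000000000000e+01,5.670065034245366675e+00
-1.468750000000000000e+01,5.699360958090381679e+00
-1.437500000000000000e+01,5.730636622764381016e+00
-1.406250000000000000e+01,5.764076205966074617e+00
-1.375000000000000000e+01,5.799886050629405432e+00
-1.343750000000000000e+01,5.838297986322370292e+00
-1.312500000000000000e+01,5.879573254853468711e+00
-1.281250000000000000e+01,5.924007171189162868e+00
-1.250000000000000000e+01,5.971934684288792816e+00
-1.218750000000000000e+01,6.023737045954566938e+00
-1.187500000000000000e+01,6.079849852725562442e+00
-1.156250000000000000e+01,6.140772800923909536e+00
-1.125000000000000000e+01,6.207081596122828060e+00
-1.093750000000000000e+01,6.279442590346201669e+00
-1.062500000000000000e+01,6.358630910728967578e+00
-1.031250000000000000e+01,6.445553089909001443e+00
-1.000000000000000000e+01,6.541275570535810324e+00
-9.687500000000000000e+00,6.647060959043052719e+00
-9.375000000000000000e+00,6.764414636236100620e+00
-9.062500000000000000e+00,6.895145410936271091e+00
-8.750000000000000000e+00,7.041445530279999865e+00
-8.437500000000000000e+00,7.205997881165265184e+00
-8.125000000000000000e+00,7.392122248675168983e+00
-7.812500000000000000e+00,7.603979200892462487e+00
-7.500000000000000000e+00,7.846861873600121662e+00
-7.187500000000000000e+00,8.127627626181336495e+00
-6.875000000000000000e+00,8.455364536021187760e+00
-6.562500000000000000e+00,8.842477589391705806e+00
-6.250000000000000000e+00,9.306567575238526402e+00
-5.937500000000000000e+00,9.873828804206995713e+00
-5.625000000000000000e+00,1.058515567538004198e+01
-5.312500000000000000e+00,1.150609364400150625e+01
-5.000000000000000000e+00,1.273932615595362705e+01
-4.687500000000000000e+00,1.443100603092478629e+01
-4.375000000000000000e+00,1.675115574685507269e+01
-4.062500000000000000e+00,1.982529684445749396e+01
-3.750000000000000000e+00,2.361808849314448722e+01
-3.437500000000000000e+00,2.782670044430830103e+01
-3.125000000000000000e+00,3.192203438541530858e+01
-2.812500000000000000e+00,3.552272329751006907e+01
-2.500000000000000000e+00,3.908979496217634164e+01
-2.187500000000000000e+00,4.465379248424213188e+01
-1.875000000000000000e+00,5.662749994962097588e+01
-1.562500000000000000e+00,8.265901363853821238e+01
-1.250000000000000000e+00,1.327900774616236959e+02
-9.375000000000000000e-01,2.142351441663579124e+02
-6.250000000000000000e-01,3.217057901776877316e+02
-3.125000000000000000e-01,4.264378471397943713e+02
0.000000000000000000e+00,4.733643834451689258e+02
3.125000000000000000e-01,4.265104144924820275e+02
6.250000000000000000e-01,3.218611760560262383e+02
9.375000000000000000e-01,2.144958018742637194e+02
1.250000000000000000e+00,1.331930120504181616e+02
1.562500000000000000e+00,8.325471036271383696e+01
1.875000000000000000e+00,5.746966239323752745e+01
2.187500000000000000e+00,4.577560434099167708e+01
2.500000000000000000e+00,4.047044080392200271e+01
2.812500000000000000e+00,3.706309315077631084e+01
3.125000000000000000e+00,3.346119274713133507e+01
3.437500000000000000e+00,2.920643351014410172e+01
3.750000000000000000e+00,2.474522539833786539e+01
4.062500000000000000e+00,2.068458983666059936e+01
4.375000000000000000e+00,1.737946232254174816e+01
4.687500000000000000e+00,1.488419641067181054e+01
5.000000000000000000e+00,1.306967286260696604e+01
5.312500000000000000e+00,1.175313352795321364e+01
5.625000000000000000e+00,1.077554584845485586e+01
5.937500000000000000e+00,1.002466589534045838e+01
6.250000000000000000e+00,9.428805066798798151e+00
6.562500000000000000e+00,8.943339810173672078e+00
6.875000000000000000e+00,8.539808109979146522e+00
7.187500000000000000e+00,8.199182032596203484e+00
7.500000000000000000e+00,7.908118301546953610e+00
7.812500000000000000e+00,7.656886854546135268e+00
8.125000000000000000e+00,7.438176607353204517e+00
8.437500000000000000e+00,7.246365344826570798e+00
8.750000000000000000e+00,7.077048731610903864e+00
9.062500000000000000e+00,6.926723182780237131e+00
9.375000000000000000e+00,6.792565098090780573e+00
9.687500000000000000e+00,6.672273054071831133e+00
1.000000000000000000e+01,6.563952522398460054e+00
1.031250000000000000e+01,6.466030097949694522e+00
1.062500000000000000e+01,6.377188668118382253e+00
1.093750000000000000e+01,6.296317729241824424e+00
1.125000000000000000e+01,6.222474842201804357e+00
1.156250000000000000e+01,6.154855400169308766e+00
1.187500000000000000e+01,6.092768680118650693e+00
1.218750000000000000e+01,6.035618700583995633e+00
1.250000000000000000e+01,5.982888794706461510e+00
1.281250000000000000e+01,5.934129083139930927e+00
1.312500000000000000e+01,5.888946230499078283e+00
1.343750000000000000e+01,5.846995014746839914e+00
1.375000000000000000e+01,5.807971346834651882e+00
1.406250000000000000e+01,5.771606458603566026e+00
1.437500000000000000e+01,5.737662037965733930e+00
1.468750000000000000e+01,5.705926136881430466e+00
1.500000000000000000e+01,5.676209713401058288e+00
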