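english_name,latin_name,nsg_c,nsg_k,nsg_t_b,nsg_t_e,bsg_c_m,bsg_t_m,bsg_t_b,bsg_t_e,wmax_nsg_ref,wmax_bsg_ref
Sunflower,Helianthus annuus,-0.049,3.872,14.191,87.525,21.810,105.101,-251.198,121.770,310.69,924.76
Peanut,Arachis hypogaea,-0.012,2.788,-8.039,88.088,1.919,127.206,-18.244,176.192,41.90,177.78
Black soybean,Glycine max,-0.023,7.015,16.458,81.110,1.599,74.514,-24.915,89.598,47.97,54.09
Garden pea,Pisum sativum,-0.023,9.727,2.284,81.174,2.267,73.590,-17.770,93.217,86.07,93.56
Adzuki bean,Vigna angularis,-0.021,0.453,13.904,71.433,0.579,54.271,26.594,85.154,23.36,22.92
Mung bean,Vigna radiata,-0.021,22.886,14.052,75.209,1.062,116.547,34.286,311.459,33.92,202.84
Cotton,Gossypium spp.,-0.032,26.624,16.679,80.116,3.465,73.278,-252.860,83.296,88.49,90.26
Sweet sorghum,Sorghum bicolor,-0.052,5.946,15.264,74.294,7.628,66.625,-54.308,76.695,186.24,186.40
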