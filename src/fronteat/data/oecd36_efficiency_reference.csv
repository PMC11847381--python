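country,phi_fdh,rec_fdh,rank_fdh,phi_eat,rec_eat,rank_eat,phi_rfeat,rec_rfeat,rank_rfeat
Canada,1.000,1.000,1,1.021,0.980,20,1.022,0.978,22
Chile,1.000,1.000,1,1.000,1.000,1,1.004,0.996,12
Colombia,1.000,1.000,1,1.055,0.948,32,1.035,0.967,28
Costa Rica,1.000,1.000,1,1.003,0.998,11,0.993,1.007,3
Mexico,1.000,1.000,1,1.000,1.000,1,1.025,0.976,24
United States,1.094,0.914,36,1.094,0.914,36,1.099,0.910,36
Japan,1.000,1.000,1,1.000,1.000,1,0.995,1.005,4
Korea Rep,1.000,1.000,1,1.000,1.000,1,0.992,1.008,1
Austria,1.023,0.977,31,1.025,0.976,26,1.028,0.973,27
Belgium,1.021,0.980,26,1.032,0.969,29,1.025,0.976,25
Czechia,1.047,0.955,33,1.070,0.935,34,1.070,0.935,33
Denmark,1.021,0.980,28,1.022,0.978,23,1.024,0.977,23
Estonia,1.022,0.978,29,1.022,0.978,22,1.042,0.960,30
Finland,1.021,0.980,26,1.021,0.980,20,1.020,0.981,21
France,1.015,0.986,24,1.015,0.986,18,1.016,0.985,19
Germany,1.010,0.990,23,1.031,0.970,28,1.036,0.965,29
Greece,1.000,1.000,1,1.010,0.990,15,1.007,0.993,13
Hungary,1.015,0.985,25,1.015,0.985,19,1.066,0.938,32
Iceland,1.000,1.000,1,1.001,0.999,9,0.998,1.002,9
Ireland,1.000,1.000,1,1.026,0.975,27,1.010,0.990,16
Israel,1.000,1.000,1,1.000,1.000,1,0.997,1.003,8
Italy,1.000,1.000,1,1.007,0.993,14,1.008,0.993,14
Latvia,1.079,0.927,35,1.079,0.927,35,1.081,0.925,34
Lithuania,1.063,0.940,34,1.063,0.940,33,1.084,0.922,35
Luxembourg,1.000,1.000,1,1.015,0.986,17,0.997,1.003,7
Netherlands,1.023,0.977,30,1.023,0.977,24,1.026,0.975,26
Norway,1.000,1.000,1,1.001,0.999,9,1.004,0.996,11
Poland,1.045,0.957,32,1.045,0.957,31,1.051,0.952,31
Portugal,1.000,1.000,1,1.037,0.965,30,1.012,0.988,17
Slovenia,1.001,0.999,19,1.024,0.977,25,1.018,0.982,20
Spain,1.000,1.000,1,1.000,1.000,1,0.996,1.004,6
Sweden,1.006,0.994,22,1.006,0.994,13,1.010,0.990,15
Switzerland,1.000,1.000,1,1.000,1.000,1,0.993,1.007,2
Turkiye,1.000,1.000,1,1.000,1.000,1,0.995,1.005,5
Australia,1.004,0.996,20,1.004,0.996,12,1.004,0.997,10
New Zealand,1.005,0.995,21,1.012,0.988,16,1.013,0.987,18
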