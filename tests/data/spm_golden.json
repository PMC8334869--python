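{
 "stat": "t",
 "dof": [
  6.0
 ],
 "fwhm": 16.646567673219113,
 "resels": 6.007244373918555,
 "critical": 5.116148308867119,
 "alpha": 0.05,
 "two_tailed": true,
 "clusters": [
  {
   "start": 40.0,
   "end": 43.0,
   "p": 0.0342522984006155
  }
 ],
 "statistic_field": [
  0.17873,
  0.15928,
  0.142822,
  0.130761,
  0.124737,
  0.126749,
  0.139017,
  0.164211,
  0.205309,
  0.266927,
  0.354775,
  0.477072,
  0.645327,
  0.873921,
  1.177215,
  1.550937,
  1.936731,
  2.207783,
  2.281847,
  2.20894,
  2.080801,
  1.951878,
  1.840896,
  1.750562,
  1.678707,
  1.621278,
  1.574975,
  1.5366,
  1.503037,
  1.471745,
  1.440611,
  1.407413,
  1.370159,
  1.326843,
  1.276168,
  1.21718,
  1.149499,
  1.07374,
  0.991383,
  0.905161,
  5.441266,
  5.373846,
  5.277661,
  5.157928,
  5.021326,
  4.874297,
  4.722952,
  4.571126,
  4.421812,
  4.276992,
  4.137864,
  4.005383,
  3.881183,
  3.76649,
  3.663289,
  3.573759,
  0.372035,
  0.369155,
  0.37049,
  0.378186,
  0.393503,
  0.417924,
  0.452706,
  0.498429,
  0.554842,
  0.620311,
  0.692507,
  0.768053,
  0.843141,
  0.914123,
  0.97891,
  1.036041,
  1.085522,
  1.12769,
  1.16332,
  1.193299,
  1.218629,
  1.240326,
  1.258784,
  1.274749,
  1.288534,
  1.300252,
  1.310087,
  1.317617,
  1.322146,
  1.321408,
  1.31249,
  1.288443,
  1.23796,
  1.144036,
  0.987985,
  0.767592,
  0.513185,
  0.272991,
  0.078579,
  -0.063933,
  -0.161714,
  -0.224761,
  -0.261825,
  -0.279167,
  -0.281047
 ]
}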