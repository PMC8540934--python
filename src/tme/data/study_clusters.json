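[
 {
  "cluster": "1",
  "initial": {
   "A": 48900.0,
   "C": 1560.0,
   "D": 0.0099,
   "DN": 0.0099,
   "E": 7.62,
   "H": 5.06,
   "IL10": 2.9,
   "IL12": 5.82,
   "IL6": 3.67,
   "Ig": 3.05,
   "M": 5370.0,
   "MN": 13400.0,
   "N": 121.0,
   "TN": 262.0,
   "Tc": 2940.0,
   "Th": 1930.0,
   "Tr": 555.0
  },
  "n_members": 2,
  "scale_max": {
   "A": 138300.0,
   "C": 168000.0,
   "D": 14745.0,
   "DN": 1605.0,
   "E": 13.74,
   "H": 11.55,
   "IL10": 7.62,
   "IL12": 10.32,
   "IL6": 9.015,
   "Ig": 8.78,
   "M": 31050.0,
   "MN": 27000.0,
   "N": 23100.0,
   "TN": 16950.0,
   "Tc": 24950.0,
   "Th": 8925.0,
   "Tr": 2880.0
  },
  "steady": {
   "A": 90100.0,
   "C": 90300.0,
   "D": 328.0,
   "DN": 126.0,
   "E": 8.86,
   "H": 5.61,
   "IL10": 3.17,
   "IL12": 6.42,
   "IL6": 3.42,
   "Ig": 3.21,
   "M": 13900.0,
   "MN": 18000.0,
   "N": 11500.0,
   "TN": 4550.0,
   "Tc": 2440.0,
   "Th": 3870.0,
   "Tr": 1920.0
  }
 },
 {
  "cluster": "2",
  "initial": {
   "A": 48600.0,
   "C": 2310.0,
   "D": 9830.0,
   "DN": 1070.0,
   "E": 8.76,
   "H": 5.01,
   "IL10": 2.93,
   "IL12": 6.4,
   "IL6": 3.02,
   "Ig": 2.93,
   "M": 11200.0,
   "MN": 2630.0,
   "N": 316.0,
   "TN": 3780.0,
   "Tc": 2950.0,
   "Th": 2160.0,
   "Tr": 504.0
  },
  "n_members": 2,
  "scale_max": {
   "A": 138300.0,
   "C": 168000.0,
   "D": 14745.0,
   "DN": 1605.0,
   "E": 13.74,
   "H": 11.55,
   "IL10": 7.62,
   "IL12": 10.32,
   "IL6": 9.015,
   "Ig": 8.78,
   "M": 31050.0,
   "MN": 27000.0,
   "N": 23100.0,
   "TN": 16950.0,
   "Tc": 24950.0,
   "Th": 8925.0,
   "Tr": 2880.0
  },
  "steady": {
   "A": 91400.0,
   "C": 112000.0,
   "D": 610.0,
   "DN": 327.0,
   "E": 4.03,
   "H": 3.84,
   "IL10": 1.36,
   "IL12": 2.84,
   "IL6": 1.28,
   "Ig": 1.19,
   "M": 16200.0,
   "MN": 6960.0,
   "N": 10200.0,
   "TN": 11300.0,
   "Tc": 4020.0,
   "Th": 4770.0,
   "Tr": 1550.0
  }
 },
 {
  "cluster": "3",
  "initial": {
   "A": 43900.0,
   "C": 3530.0,
   "D": 0.0362,
   "DN": 3.22,
   "E": 9.16,
   "H": 5.29,
   "IL10": 2.79,
   "IL12": 5.25,
   "IL6": 4.27,
   "Ig": 2.81,
   "M": 9670.0,
   "MN": 6750.0,
   "N": 311.0,
   "TN": 2930.0,
   "Tc": 1390.0,
   "Th": 1150.0,
   "Tr": 36.8
  },
  "n_members": 2,
  "scale_max": {
   "A": 138300.0,
   "C": 168000.0,
   "D": 14745.0,
   "DN": 1605.0,
   "E": 13.74,
   "H": 11.55,
   "IL10": 7.62,
   "IL12": 10.32,
   "IL6": 9.015,
   "Ig": 8.78,
   "M": 31050.0,
   "MN": 27000.0,
   "N": 23100.0,
   "TN": 16950.0,
   "Tc": 24950.0,
   "Th": 8925.0,
   "Tr": 2880.0
  },
  "steady": {
   "A": 88000.0,
   "C": 96800.0,
   "D": 352.0,
   "DN": 400.0,
   "E": 7.68,
   "H": 4.49,
   "IL10": 2.13,
   "IL12": 4.02,
   "IL6": 2.14,
   "Ig": 1.97,
   "M": 20700.0,
   "MN": 8770.0,
   "N": 8110.0,
   "TN": 5730.0,
   "Tc": 2790.0,
   "Th": 3700.0,
   "Tr": 1510.0
  }
 },
 {
  "cluster": "4",
  "initial": {
   "A": 44900.0,
   "C": 7960.0,
   "D": 1340.0,
   "DN": 351.0,
   "E": 6.38,
   "H": 5.29,
   "IL10": 3.27,
   "IL12": 6.88,
   "IL6": 3.4,
   "Ig": 4.1,
   "M": 4690.0,
   "MN": 2290.0,
   "N": 2710.0,
   "TN": 4780.0,
   "Tc": 2760.0,
   "Th": 4600.0,
   "Tr": 1660.0
  },
  "n_members": 2,
  "scale_max": {
   "A": 138300.0,
   "C": 168000.0,
   "D": 14745.0,
   "DN": 1605.0,
   "E": 13.74,
   "H": 11.55,
   "IL10": 7.62,
   "IL12": 10.32,
   "IL6": 9.015,
   "Ig": 8.78,
   "M": 31050.0,
   "MN": 27000.0,
   "N": 23100.0,
   "TN": 16950.0,
   "Tc": 24950.0,
   "Th": 8925.0,
   "Tr": 2880.0
  },
  "steady": {
   "A": 92200.0,
   "C": 95400.0,
   "D": 437.0,
   "DN": 499.0,
   "E": 1.37,
   "H": 7.54,
   "IL10": 5.08,
   "IL12": 1.04,
   "IL6": 5.8,
   "Ig": 5.72,
   "M": 15900.0,
   "MN": 9810.0,
   "N": 15400.0,
   "TN": 4140.0,
   "Tc": 7710.0,
   "Th": 5950.0,
   "Tr": 1660.0
  }
 },
 {
  "cluster": "5",
  "initial": {
   "A": 37400.0,
   "C": 5570.0,
   "D": 0.0103,
   "DN": 516.0,
   "E": 8.63,
   "H": 6.16,
   "IL10": 2.66,
   "IL12": 5.67,
   "IL6": 3.03,
   "Ig": 2.7,
   "M": 6070.0,
   "MN": 2850.0,
   "N": 373.0,
   "TN": 3780.0,
   "Tc": 3110.0,
   "Th": 1330.0,
   "Tr": 1050.0
  },
  "n_members": 2,
  "scale_max": {
   "A": 138300.0,
   "C": 168000.0,
   "D": 14745.0,
   "DN": 1605.0,
   "E": 13.74,
   "H": 11.55,
   "IL10": 7.62,
   "IL12": 10.32,
   "IL6": 9.015,
   "Ig": 8.78,
   "M": 31050.0,
   "MN": 27000.0,
   "N": 23100.0,
   "TN": 16950.0,
   "Tc": 24950.0,
   "Th": 8925.0,
   "Tr": 2880.0
  },
  "steady": {
   "A": 76700.0,
   "C": 99000.0,
   "D": 222.0,
   "DN": 704.0,
   "E": 1.5,
   "H": 7.7,
   "IL10": 5.05,
   "IL12": 1.02,
   "IL6": 6.01,
   "Ig": 5.17,
   "M": 15200.0,
   "MN": 6450.0,
   "N": 15300.0,
   "TN": 5690.0,
   "Tc": 5560.0,
   "Th": 3910.0,
   "Tr": 616.0
  }
 }
]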