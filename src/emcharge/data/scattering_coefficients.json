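{
  "version": "1.0",
  "electron_5g": {
    "source": "Peng, Ren, Dudarev & Whelan (1996) Acta Cryst. A52 257-276; five-Gaussian elastic electron scattering factors for neutral atoms (International Tables for Crystallography Vol. C, Table 4.3.2.2 lineage). f(s) = sum_i a_i exp(-b_i s^2), s = sin(theta)/lambda in 1/A, f in A.",
    "entries": {
      "H":  {"Z": 1,  "a": [0.0349, 0.1201, 0.1970, 0.0573, 0.1195], "b": [0.5347, 3.5867, 12.3471, 18.9525, 38.6269]},
      "C":  {"Z": 6,  "a": [0.0893, 0.2563, 0.7570, 1.0487, 0.3575], "b": [0.2465, 1.7100, 6.4094, 18.6113, 50.2523]},
      "N":  {"Z": 7,  "a": [0.1022, 0.3219, 0.7982, 0.8197, 0.1715], "b": [0.2451, 1.7481, 6.1925, 17.3894, 48.1431]},
      "O":  {"Z": 8,  "a": [0.0974, 0.2921, 0.6910, 0.6990, 0.2039], "b": [0.2067, 1.3815, 4.6943, 12.7105, 32.4726]},
      "S":  {"Z": 16, "a": [0.2497, 0.5628, 1.3899, 2.1865, 0.7715], "b": [0.2681, 1.6711, 7.0267, 19.5377, 50.3888]}
    }
  },
  "xray_4g": {
    "source": "International Tables for Crystallography Vol. C, Table 6.1.1.4 (IT92); four-Gaussian + constant X-ray form factors for neutral atoms and ions. f(s) = sum_i a_i exp(-b_i s^2) + c; f(0) = electron count.",
    "entries": {
      "H":   {"Z": 1,  "charge": 0,  "a": [0.4930, 0.3229, 0.1402, 0.0408], "b": [10.5109, 26.1257, 3.1424, 57.7997], "c": 0.0030},
      "C":   {"Z": 6,  "charge": 0,  "a": [2.3100, 1.0200, 1.5886, 0.8650], "b": [20.8439, 10.2075, 0.5687, 51.6512], "c": 0.2156},
      "N":   {"Z": 7,  "charge": 0,  "a": [12.2126, 3.1322, 2.0125, 1.1663], "b": [0.0057, 9.8933, 28.9975, 0.5826], "c": -11.5290},
      "O":   {"Z": 8,  "charge": 0,  "a": [3.0485, 2.2868, 1.5463, 0.8670], "b": [13.2771, 5.7011, 0.3239, 32.9089], "c": 0.2508},
      "O1-": {"Z": 8,  "charge": -1, "a": [4.1916, 1.63969, 1.52673, -20.307], "b": [12.8573, 4.17236, 47.0179, -0.01404], "c": 21.9412},
      "S":   {"Z": 16, "charge": 0,  "a": [6.9053, 5.2034, 1.4379, 1.5863], "b": [1.4679, 22.2151, 0.2536, 56.1720], "c": 0.8669}
    }
  }
}
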