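{
  "description": "Published per-batch content (% of the nominal 50 mg/ml total saponins) of the 27 characteristic peaks across ten production batches S1-S10.",
  "batches": ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10"],
  "contents": {
    "1":  [6.64, 5.29, 6.89, 6.47, 6.27, 5.86, 5.33, 6.41, 6.07, 6.35],
    "2":  [25.43, 20.50, 24.53, 23.99, 23.76, 20.29, 21.15, 22.23, 22.31, 23.33],
    "3":  [3.43, 2.91, 4.92, 3.61, 3.55, 3.56, 3.35, 3.04, 3.03, 3.69],
    "4":  [1.52, 1.19, 1.24, 1.33, 1.28, 1.33, 1.31, 1.11, 1.15, 1.38],
    "5":  [1.24, 0.95, 0.98, 1.15, 1.15, 0.97, 1.03, 1.03, 1.03, 1.00],
    "6":  [1.45, 1.21, 1.90, 1.35, 1.44, 1.43, 1.35, 1.29, 1.29, 1.34],
    "7":  [0.89, 0.62, 0.17, 0.80, 0.80, 0.76, 0.81, 0.73, 0.66, 0.83],
    "8":  [0.65, 0.51, 2.28, 0.56, 0.62, 0.46, 0.54, 0.52, 0.49, 0.54],
    "9":  [28.39, 26.17, 26.34, 28.30, 28.78, 29.58, 29.60, 28.00, 28.14, 27.78],
    "10": [1.30, 0.94, 0.99, 1.13, 1.12, 1.06, 0.98, 1.05, 1.05, 1.15],
    "11": [1.02, 1.31, 1.08, 1.18, 0.98, 0.78, 1.44, 1.38, 1.38, 1.17],
    "12": [1.77, 3.06, 2.25, 2.22, 1.65, 1.06, 2.90, 3.19, 3.22, 2.17],
    "13": [1.09, 0.69, 2.18, 1.07, 1.06, 1.00, 0.90, 0.81, 1.11, 1.04],
    "14": [0.76, 1.77, 0.29, 1.14, 0.85, 0.50, 1.59, 1.90, 1.88, 1.24],
    "15": [7.50, 6.82, 7.25, 7.22, 7.24, 7.27, 8.10, 7.41, 7.48, 7.18],
    "16": [1.01, 0.72, 1.05, 1.18, 1.24, 1.33, 1.36, 0.96, 1.04, 1.43],
    "17": [0.39, 0.69, 0.58, 0.69, 0.47, 0.39, 0.79, 0.87, 0.86, 0.83],
    "18": [0.30, 0.37, 1.11, 0.45, 0.36, 0.23, 0.56, 0.50, 0.50, 0.46],
    "19": [0.72, 1.31, 0.41, 1.19, 0.82, 0.63, 1.51, 1.51, 1.54, 1.20],
    "20": [0.39, 0.55, 0.31, 0.55, 0.37, 0.39, 0.70, 0.66, 0.67, 0.55],
    "21": [0.90, 2.30, 1.59, 1.78, 1.10, 0.80, 2.35, 2.52, 2.57, 1.77],
    "22": [1.27, 3.66, 2.47, 2.69, 1.49, 0.91, 3.70, 3.87, 3.88, 2.65],
    "23": [0.37, 1.01, 0.75, 0.81, 0.44, 0.43, 1.21, 1.09, 1.14, 0.83],
    "24": [0.21, 0.70, 0.52, 0.51, 0.25, 0.22, 0.78, 0.76, 0.82, 0.56],
    "25": [0.36, 0.38, 0.23, 0.28, 0.14, 0.10, 0.78, 0.42, 0.43, 0.25],
    "26": [0.41, 1.13, 1.22, 0.81, 0.66, 0.47, 1.62, 1.02, 1.28, 0.80],
    "27": [0.32, 1.30, 1.17, 1.05, 0.65, 0.46, 1.95, 1.31, 1.50, 1.03]
  }
}
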