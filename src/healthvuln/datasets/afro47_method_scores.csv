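country,polychoric_pca,efa,entropy,equal,equal_with_poverty
Algeria,35.71,38.06,42.88,47.50,48.00
Angola,35.71,38.06,42.88,47.50,48.00
Benin,71.03,68.31,64.75,63.33,64.67
Botswana,27.69,30.76,36.68,41.25,38.00
Burkina Faso,56.87,55.25,52.97,52.08,60.67
Burundi,88.16,87.90,88.80,90.00,96.00
Cabo Verde,36.99,39.09,41.45,42.92,43.33
Cameroon,59.18,59.45,59.43,60.42,62.33
Central African Republic,79.49,78.27,76.79,76.67,75.33
Chad,70.81,68.65,64.77,63.33,74.67
Comoros,65.97,67.54,70.82,72.50,67.00
Congo,81.80,82.48,83.24,85.00,82.00
Côte d’Ivoire,48.84,47.95,46.77,45.83,45.67
Democratic Republic of the Congo,71.03,68.31,64.75,63.33,74.67
Equatorial Guinea,27.69,30.76,36.68,41.25,43.00
Eritrea,73.35,72.51,71.21,71.67,71.33
Eswatini,43.57,44.17,46.99,47.92,48.33
Ethiopia,85.41,84.37,82.39,81.67,89.33
Gabon,22.62,23.03,23.81,24.58,24.67
Gambia,73.35,72.51,71.21,71.67,66.33
Ghana,65.32,65.21,65.01,65.42,61.33
Guinea,56.87,55.25,52.97,52.08,60.67
Guinea-Bissau,65.32,65.21,65.01,65.42,61.33
Kenya,57.30,57.91,58.81,59.17,56.33
Lesotho,60.05,61.44,65.22,67.50,63.00
Liberia,59.83,61.78,65.24,67.50,73.00
Madagascar,73.57,72.17,71.19,71.67,81.33
Malawi,91.55,90.13,87.97,86.67,93.33
Mali,55.15,54.89,54.45,56.67,59.33
Mauritania,48.84,47.95,46.77,45.83,50.67
Mauritius,25.15,26.89,30.25,32.92,36.33
Mozambique,85.63,84.03,82.37,81.67,89.33
Namibia,27.69,30.76,36.68,41.25,38.00
Niger,73.35,72.51,71.21,71.67,81.33
Nigeria,30.64,30.33,30.01,30.83,29.67
Rwanda,63.01,61.01,58.55,57.08,64.67
Sao Tome and Principe,61.33,62.47,63.79,62.92,59.33
Senegal,56.87,55.25,52.97,52.08,50.67
Seychelles,22.62,23.03,23.81,24.58,29.67
Sierra Leone,79.49,78.27,76.79,76.67,80.33
South Africa,27.69,30.76,36.68,41.25,38.00
South Sudan,88.16,87.90,88.80,90.00,96.00
Togo,70.81,68.65,64.77,63.33,64.67
Uganda,71.03,68.31,64.75,63.33,69.67
United Republic of Tanzania,65.11,62.21,59.15,58.33,61.67
Zambia,77.38,77.07,76.19,75.42,79.33
Zimbabwe,83.52,82.83,81.77,80.42,78.33
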