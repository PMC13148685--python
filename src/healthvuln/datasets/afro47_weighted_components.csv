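country,che_component,fad_component,bsp_component,ctb_component,overall_score,archetype
Malawi,32.10,30.70,5.07,23.68,91.55,Very High
Burundi,32.10,30.70,7.60,17.76,88.16,Very High
South Sudan,32.10,30.70,7.60,17.76,88.16,Very High
Mozambique,32.10,30.70,5.07,17.76,85.63,Very High
Ethiopia,32.10,24.56,5.07,23.68,85.41,Very High
Zimbabwe,24.08,30.70,5.07,23.68,83.52,Very High
Congo,32.10,18.42,7.60,23.68,81.80,Very High
Central African Republic,32.10,24.56,5.07,17.76,79.49,Very High
Sierra Leone,32.10,24.56,5.07,17.76,79.49,Very High
Zambia,24.08,24.56,5.07,23.68,77.38,Very High
Madagascar,32.10,24.56,5.07,11.84,73.57,Very High
Eritrea,32.10,18.42,5.07,17.76,73.35,Very High
Gambia,32.10,18.42,5.07,17.76,73.35,Very High
Niger,32.10,18.42,5.07,17.76,73.35,Very High
Benin,32.10,24.56,2.53,11.84,71.03,High
Democratic Republic of the Congo,32.10,24.56,2.53,11.84,71.03,High
Uganda,32.10,24.56,2.53,11.84,71.03,High
Chad,32.10,18.42,2.53,17.76,70.81,High
Togo,32.10,18.42,2.53,17.76,70.81,High
Comoros,16.05,24.56,7.60,17.76,65.97,High
Ghana,24.08,18.42,5.07,17.76,65.32,High
Guinea-Bissau,24.08,18.42,5.07,17.76,65.32,High
United Republic of Tanzania,32.10,24.56,2.53,5.92,65.11,High
Rwanda,24.08,24.56,2.53,11.84,63.01,High
Sao Tome and Principe,8.03,24.56,5.07,23.68,61.33,High
Lesotho,16.05,24.56,7.60,11.84,60.05,High
Liberia,16.05,18.42,7.60,17.76,59.83,High
Cameroon,24.08,12.28,5.07,17.76,59.18,Moderate
Kenya,16.05,18.42,5.07,17.76,57.30,Moderate
Burkina Faso,24.08,18.42,2.53,11.84,56.87,Moderate
Guinea,24.08,18.42,2.53,11.84,56.87,Moderate
Senegal,24.08,18.42,2.53,11.84,56.87,Moderate
Mali,32.10,6.14,5.07,11.84,55.15,Moderate
Côte d’Ivoire,16.05,18.42,2.53,11.84,48.84,Moderate
Mauritania,16.05,18.42,2.53,11.84,48.84,Moderate
Eswatini,8.03,24.56,5.07,5.92,43.57,Moderate
Cabo Verde,8.03,6.14,5.07,17.76,36.99,Low
Algeria,16.05,6.14,7.60,5.92,35.71,Low
Angola,16.05,6.14,7.60,5.92,35.71,Low
Nigeria,16.05,6.14,2.53,5.92,30.64,Low
Botswana,8.03,6.14,7.60,5.92,27.69,Low
Equatorial Guinea,8.03,6.14,7.60,5.92,27.69,Low
Namibia,8.03,6.14,7.60,5.92,27.69,Low
South Africa,8.03,6.14,7.60,5.92,27.69,Low
Mauritius,8.03,6.14,5.07,5.92,25.15,Low
Gabon,8.03,6.14,2.53,5.92,22.62,Low
Seychelles,8.03,6.14,2.53,5.92,22.62,Low
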