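name,kind,p_response,p_response_low,p_response_high,annual_disc,annual_disc_low,annual_disc_high,u_resp,u_resp_low,u_resp_high,u_nonresp,u_nonresp_low,u_nonresp_high,monitor_cycle,monitor_low,monitor_high,vial_cost,vial_cost_low,vial_cost_high,flat_cycle_cost,flat_low,flat_high,admin_model
SEC,biologic,0.85,0.83,0.88,0.22,0.18,0.26,0.85,0.68,1.00,0.62,0.50,0.74,168,134.18,201,3555,2844,4266,,,,per_injection
UST,biologic,0.70,0.65,0.74,0.20,0.16,0.24,0.85,0.68,1.00,0.62,0.50,0.74,168,134.18,201,10379,8303,12455,,,,per_injection
ADA,biologic,0.70,0.66,0.73,0.21,0.17,0.25,0.85,0.68,1.00,0.62,0.50,0.74,168,134.18,201,1481,1185,1778,,,,once_only
ADA_BS,biologic,0.70,0.66,0.73,0.21,0.17,0.25,0.85,0.68,1.00,0.62,0.50,0.74,168,134.18,201,886,709,1063,,,,once_only
SYS,systemic,0.42,0.27,0.54,0.38,0.30,0.46,0.89,0.71,1.00,0.64,0.51,0.77,299,239.37,359,,,,1183,946,1420,none
PHOTO,phototherapy,0.32,0.18,0.26,0.49,0.39,0.59,0.89,0.71,1.00,0.64,0.51,0.77,185,147.73,222,,,,1427,1141,1712,sessions_per_week
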