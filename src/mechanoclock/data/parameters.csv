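module,name,value,units,fit_lo,fit_hi,source
mechano,FAK_tot,1.0,model units,,,package point estimate
mechano,k_f0,0.015,1/h,,,package point estimate
mechano,k_sf,0.25,1/h,,,package point estimate
mechano,C_E,10.0,kPa,,,package point estimate
mechano,n_stiff_exp,0.5,model units,,,package point estimate
mechano,k_df,0.12,1/h,,,package point estimate
mechano,A_0,3000.0,um^2,,,package point estimate
mechano,K_A,1800.0,um^2,,,package point estimate
mechano,density_fak_factor,0.55,model units,,,package point estimate
mechano,density_lats_factor,2.5,model units,,,package point estimate
mechano,RhoA_tot,1.0,model units,,,package point estimate
mechano,k_fkrho,1.0,1/h,,,package point estimate
mechano,gamma_fak,1.8,model units,,,package point estimate
mechano,n_fak_exp,4.0,model units,,,package point estimate
mechano,k_drho,2.0,1/h,,,package point estimate
mechano,ROCK_tot,1.0,model units,,,package point estimate
mechano,k_rrho,2.2,1/h,,,package point estimate
mechano,k_drock,1.5,1/h,,,package point estimate
mechano,mDia_tot,1.0,model units,,,package point estimate
mechano,k_mrho,2.5,1/h,,,package point estimate
mechano,k_dmdia,1.5,1/h,,,package point estimate
mechano,LIMK_tot,1.0,model units,,,package point estimate
mechano,k_lk,2.0,1/h,,,package point estimate
mechano,k_dlimk,0.8,1/h,,,package point estimate
mechano,Cof_tot,1.0,model units,,,package point estimate
mechano,k_cof_on,0.2,1/h,,,package point estimate
mechano,k_lc,1.0,1/h,,,package point estimate
mechano,Myo_tot,1.5,model units,,,package point estimate
mechano,k_mr,2.0,1/h,,,package point estimate
mechano,k_dmyo,1.0,1/h,,,package point estimate
mechano,Actin_tot,1.0,model units,,,package point estimate
mechano,A_poly,1.0,model units,,,package point estimate
mechano,k_poly0,0.05,1/h,,,package point estimate
mechano,k_mdia,1.6,1/h,,,package point estimate
mechano,k_dep,0.3,1/h,,,package point estimate
mechano,k_sev,2.5,1/h,,,package point estimate
mechano,k_capC,4.0,1/h,1.0,10.0,package point estimate
mechano,k_uncap,1.0,1/h,,,package point estimate
mechano,k_dimC,4.0,1/h,1.0,10.0,package point estimate
mechano,k_undim,1.0,1/h,,,package point estimate
mechano,k_onL,10.0,1/h,3.0,30.0,package point estimate
mechano,k_offL,1.0,1/h,,,package point estimate
mechano,e_jas_p,6.0,model units,,,package point estimate
mechano,e_jas_d,0.75,model units,,,package point estimate
mechano,K2_jas,1.0,model units,0.3,3.0,package point estimate
mechano,K_y27,1.0,model units,0.3,3.0,package point estimate
mechano,n_y27_exp,2.0,model units,,,package point estimate
mechano,K_bleb,2.0,model units,,,package point estimate
mechano,n_bleb_exp,2.0,model units,,,package point estimate
mechano,E_c0,0.1,kPa,,,package point estimate
mechano,E_cmax,7.0,kPa,,,package point estimate
mechano,K_EF,0.6,model units,,,package point estimate
mechano,n_EF_exp,2.0,model units,,,package point estimate
mechano,LamA_tot,1.0,model units,,,package point estimate
mechano,k_lam_deph,1.0,1/h,,,package point estimate
mechano,K_lamE,2.0,kPa,,,package point estimate
mechano,n_lam_exp,2.0,model units,,,package point estimate
mechano,k_lam_p,0.5,1/h,,,package point estimate
mechano,NPC_tot,1.0,model units,,,package point estimate
mechano,k_npc_open,8.0,1/h,,,package point estimate
mechano,k_npc_close,1.0,1/h,,,package point estimate
mechano,Y_tot,2.0,model units,,,package point estimate
mechano,Y5SA_tot,0.0,model units,,,package point estimate
mechano,k_yphos,2.608,1/h,,,package point estimate
mechano,k_ydeph0,0.2,1/h,,,package point estimate
mechano,k_ydeph_F,20.16,1/h,,,package point estimate
mechano,k_yin0,0.1261,1/h,,,package point estimate
mechano,k_yin_npc,0.3082,1/h,,,package point estimate
mechano,k_yout,0.8,1/h,,,package point estimate
mechano,M_tot,2.0,model units,,,package point estimate
mechano,K_gm,0.45,model units,0.1,1.5,package point estimate
mechano,n_gm_exp,2.0,model units,,,package point estimate
mechano,k_min0,0.8,1/h,0.2,2.0,package point estimate
mechano,k_min_npc,0.8,1/h,0.1,2.0,package point estimate
mechano,k_mout,0.8,1/h,0.2,2.0,package point estimate
mechano,nuc_vol_ratio,0.4,model units,,,package point estimate
circadian,tau_B,12.0,h,8.0,16.0,package point estimate
circadian,tau_P,9.0,h,6.0,12.0,package point estimate
circadian,tau_R,4.0,h,2.0,8.0,package point estimate
circadian,K_dB,0.12,1/h,0.05,0.3,package point estimate
circadian,K_dP,0.3,1/h,0.1,0.6,package point estimate
circadian,K_dR,0.12,1/h,0.05,0.3,package point estimate
circadian,K_dL,0.3,1/h,0.1,0.6,package point estimate
circadian,K_eB0,2.0,model units,0.5,5.0,package point estimate
circadian,K_IR,1.0,model units,0.3,3.0,package point estimate
circadian,K_eP0,5.0,model units,1.0,12.0,package point estimate
circadian,K_aB,1.0,model units,0.3,3.0,package point estimate
circadian,K_IP,0.6,model units,0.2,2.0,package point estimate
circadian,zeta,0.5,model units,0.1,2.0,package point estimate
circadian,K_eB2_Y,0.075,model units,0.0,0.3,package point estimate
circadian,K_eB2_M,0.0209,model units,0.0,0.3,package point estimate
circadian,K_eP2_Y,1.5,model units,0.0,4.0,package point estimate
circadian,K_eP2_M,0.4184,model units,0.0,2.0,package point estimate
circadian,K_eR2_Y,0.6,model units,0.0,1.6,package point estimate
circadian,K_eR2_M,0.1674,model units,0.0,0.8,package point estimate
circadian,K_Y,1.7885,model units,0.5,5.0,package point estimate
circadian,K_M,4.5663,model units,0.5,8.0,package point estimate
circadian,K_eL,1.0,model units,0.5,2.0,package point estimate
circadian,n_hill,2.0,model units,,,package point estimate
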